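import numpy as np
import pytest

import lidquant as lq


@pytest.fixture(scope="session")
def default_photometry_session():
    """One synthetic photometry session under default study conditions."""
    cfg = lq.SimConfig(seed=11)
    rec, truth = lq.gen_photometry_session(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def isolated_event_session():
    """Low-rate, high-SNR session: events rarely overlap, so detector
    quality can be scored against ground truth."""
    p = lq.synth.PhotometryParams(
        transient_rate_baseline_per_min=1.0,
        response=lq.synth.ResponseProfile(plateau_gain=0.0))
    cfg = lq.SimConfig(seed=21, photometry=p)
    rec, truth = lq.gen_photometry_session(cfg)
    return cfg, rec, truth


def match_events(detected, truth, tol_s):
    """Greedy one-to-one matching; returns (n_matched, sensitivity, fdr)."""
    truth = np.asarray(truth, float)
    used = np.zeros(truth.size, bool)
    tp = 0
    for t in np.asarray(detected, float):
        d = np.abs(truth - t)
        d[used] = np.inf
        if d.size and d.min() <= tol_s:
            used[np.argmin(d)] = True
            tp += 1
    sens = tp / truth.size if truth.size else 1.0
    fdr = 1.0 - tp / len(detected) if len(detected) else 0.0
    return tp, sens, fdr
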
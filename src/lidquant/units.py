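"""In vivo single-unit screening and levodopa-response classification.

Sorted units are screened on a refractory-period criterion (single-unit
quality) and split into putative medium spiny neurons (MSNs) versus putative
interneurons by spike-waveform features; only putative MSNs enter response
classification.  A unit's firing rate in half-open 1-minute bins over the
30-minute pre-injection baseline is compared with the 10-40 minute
post-injection window using a two-sided Wilcoxon rank-sum (Mann-Whitney)
test; units with p below the significance criterion (default 0.01) are
labeled by the direction of the mean rate change — increases as putative
D1-MSNs, decreases as putative D2-MSNs — and the rest as no-change units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu

logger = logging.getLogger(__name__)

__all__ = [
    "UnitRecording",
    "UnitClassification",
    "screen_unit",
    "classify_response",
    "response_delta",
    "binned_rates",
]

BASELINE_WINDOW_MIN = (-30.0, 0.0)
POST_WINDOW_MIN = (10.0, 40.0)
ONSET_WINDOW_MIN = (0.0, 20.0)


@dataclass
class UnitRecording:
    """Spike times (seconds, injection at t = 0) plus waveform features for
    one sorted unit."""

    spike_times: np.ndarray
    peak_to_valley_ms: float
    peak_width_ms: float
    unit_id: str = ""
    subject: str = ""
    treatment_timepoint: str = ""
    session_span_s: tuple | None = None   # (start, end); None -> unchecked

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size and np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike times must be strictly increasing")
        if self.peak_to_valley_ms <= 0 or self.peak_width_ms <= 0:
            raise ValueError("waveform durations must be positive")


@dataclass
class UnitClassification:
    """Screening and response-classification outcome for one unit."""

    unit_id: str
    su_pass: bool
    isi_violation_fraction: float
    cell_type: str                      # putative_MSN | putative_interneuron
    response: str                       # increase | decrease | none
    p_value: float
    baseline_rate_hz: float
    post_rate_hz: float
    delta_rate_hz: float                # onset-window mean minus baseline


def screen_unit(u: UnitRecording, refractory_ms: float = 2.0,
                max_violation: float = 0.01, min_spikes: int = 100,
                msn_peak_to_valley_ms: float = 0.3) -> tuple:
    """Single-unit screening.

    Returns ``(su_pass, cell_type, violation_fraction)``.  A unit passes if
    fewer than ``max_violation`` of its inter-spike intervals fall inside
    the refractory period.  Units whose waveform peak-to-valley duration is
    at least ``msn_peak_to_valley_ms`` (default 0.3 ms) are classed as
    putative MSNs, shorter ones as putative interneurons; the threshold is
    a configurable prior-work convention and is logged on use.
    """
    if u.spike_times.size == 0:
        raise ValueError("empty spike train")
    if u.spike_times.size < min_spikes:
        logger.warning("unit %s has %d spikes (< %d floor)", u.unit_id,
                       u.spike_times.size, min_spikes)
    isi = np.diff(u.spike_times)
    frac = float(np.mean(isi < refractory_ms / 1000.0)) if isi.size else 0.0
    su_pass = frac < max_violation
    cell_type = ("putative_MSN" if u.peak_to_valley_ms >= msn_peak_to_valley_ms
                 else "putative_interneuron")
    logger.debug("unit %s: violation %.4f, waveform split at %.2f ms -> %s",
                 u.unit_id, frac, msn_peak_to_valley_ms, cell_type)
    return su_pass, cell_type, frac


def binned_rates(spike_times: np.ndarray, window_min, bin_s: float = 60.0
                 ) -> np.ndarray:
    """Firing rate (Hz) in half-open bins tiling ``window_min`` (minutes)."""
    a, b = float(window_min[0]) * 60.0, float(window_min[1]) * 60.0
    edges = np.arange(a, b + bin_s / 2, bin_s)
    counts, _ = np.histogram(spike_times, bins=edges)
    return counts / bin_s


def classify_response(u: UnitRecording,
                      baseline_window_min=BASELINE_WINDOW_MIN,
                      post_window_min=POST_WINDOW_MIN,
                      alpha: float = 0.01,
                      onset_window_min=ONSET_WINDOW_MIN,
                      screen_kwargs: dict | None = None
                      ) -> UnitClassification:
    """Classify a unit's levodopa response.

    Rates in 1-minute bins over the baseline and post windows are compared
    with a two-sided, tie-corrected Mann-Whitney test; ``p < alpha`` yields
    ``increase`` or ``decrease`` by the sign of the mean rate change
    (pathological significant-but-zero-difference ties are classified
    ``none`` and logged).  The recording must cover both windows.
    """
    t = u.spike_times
    if t.size == 0:
        raise ValueError("empty spike train")
    if u.session_span_s is not None:
        lo, hi = u.session_span_s
        for name, win in (("baseline", baseline_window_min),
                          ("post", post_window_min)):
            if lo > win[0] * 60.0 or hi < win[1] * 60.0:
                raise ValueError(
                    f"recording span [{lo / 60.0:g}, {hi / 60.0:g}] min does "
                    f"not cover the {name} window "
                    f"[{win[0]:g}, {win[1]:g}] min")

    base = binned_rates(t, baseline_window_min)
    post = binned_rates(t, post_window_min)
    if np.ptp(np.concatenate([base, post])) == 0.0:
        p = 1.0
    else:
        p = float(mannwhitneyu(base, post, alternative="two-sided",
                               method="asymptotic").pvalue)
    diff = float(post.mean() - base.mean())
    if p < alpha and diff > 0:
        response = "increase"
    elif p < alpha and diff < 0:
        response = "decrease"
    else:
        if p < alpha:
            logger.info("unit %s: significant rank-sum but zero mean "
                        "difference; classified none", u.unit_id)
        response = "none"

    su_pass, cell_type, frac = screen_unit(u, **(screen_kwargs or {}))
    onset = binned_rates(t, onset_window_min)
    return UnitClassification(
        unit_id=u.unit_id, su_pass=su_pass, isi_violation_fraction=frac,
        cell_type=cell_type, response=response, p_value=p,
        baseline_rate_hz=float(base.mean()), post_rate_hz=float(post.mean()),
        delta_rate_hz=float(onset.mean() - base.mean()))


def response_delta(u: UnitRecording, onset_window_min=ONSET_WINDOW_MIN,
                   baseline_window_min=BASELINE_WINDOW_MIN) -> float:
    """Mean firing rate over the dyskinesia onset window minus the mean
    baseline rate, in Hz."""
    base = binned_rates(u.spike_times, baseline_window_min)
    onset = binned_rates(u.spike_times, onset_window_min)
    return float(onset.mean() - base.mean())
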
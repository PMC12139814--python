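"""Photometry preprocessing, transient detection, and session metrics."""

import numpy as np
import pytest

import lidquant as lq
from lidquant.photometry import (PhotometryOptions, PhotometryRecording,
                                 DffTrace, TransientSeries, bin_dff,
                                 detect_transients, preprocess_dff,
                                 session_metrics)
from lidquant.synth import PhotometryParams, ResponseProfile, SimConfig

from conftest import match_events


def make_trace(dff_values, fs=20.0, t0=-1800.0):
    t = t0 + np.arange(len(dff_values)) / fs
    return DffTrace(t=t, dff=np.asarray(dff_values, float))


def single_bump_trace(amplitude, fs=20.0, width_s=4.0, n_s=120.0):
    """Noise-free trace, one smooth excursion of exact valley-to-peak
    ``amplitude`` starting from a flat zero baseline."""
    t = np.arange(0.0, n_s, 1.0 / fs)
    bump = np.exp(-0.5 * ((t - n_s / 2) / width_s) ** 2)
    return DffTrace(t=t, dff=amplitude * bump / bump.max())


class TestPreprocess:
    def test_identical_channels_give_zero_dff(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 600, 0.05) - 300.0
        shared = 50.0 + np.cumsum(rng.normal(0, 0.01, t.size))
        rec = PhotometryRecording(t=t, f465=shared, f405=shared.copy(),
                                  meta={"indicator": "GCaMP6s"})
        dff = preprocess_dff(rec)
        assert np.allclose(dff.dff, 0.0, atol=1e-9)

    def test_exact_linear_artifact_relation_gives_zero_dff(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 600, 0.05) - 300.0
        artifact = 30.0 + np.cumsum(rng.normal(0, 0.02, t.size))
        rec = PhotometryRecording(t=t, f465=2.0 * artifact + 3.0,
                                  f405=artifact, meta={"indicator": "GCaMP6s"})
        dff = preprocess_dff(rec)
        assert np.allclose(dff.dff, 0.0, atol=1e-9)

    def test_constant_isosbestic_falls_back_with_warning(self):
        t = np.arange(0, 120, 0.05) - 60.0
        rec = PhotometryRecording(t=t, f465=np.full(t.size, 40.0),
                                  f405=np.full(t.size, 10.0),
                                  meta={"indicator": "GCaMP6s"})
        with pytest.warns(RuntimeWarning, match="intercept-only"):
            dff = preprocess_dff(rec)
        assert dff.processing["isosbestic_fit"]["degenerate"]
        assert np.allclose(dff.dff, 0.0, atol=1e-9)

    def test_bleach_tau_recovered_within_5_percent(self):
        p = PhotometryParams(bleach_tau_465_min=60.0,
                             transient_rate_baseline_per_min=2.0,
                             response=ResponseProfile(plateau_gain=0.0))
        rec, _ = lq.gen_photometry_session(SimConfig(seed=2, photometry=p))
        dff = preprocess_dff(rec)
        tau_min = dff.processing["bleach_fit"]["tau_s"] / 60.0
        assert tau_min == pytest.approx(60.0, rel=0.05)

    def test_processing_record_reproduces_trace(self):
        cfg = SimConfig(seed=7, photometry=PhotometryParams(
            sampling_rate_hz=5.0))
        rec, _ = lq.gen_photometry_session(cfg)
        d1 = preprocess_dff(rec)
        d2 = preprocess_dff(rec)
        assert np.array_equal(d1.dff, d2.dff)
        assert d1.processing == d2.processing

    def test_nonfinite_input_rejected(self):
        t = np.arange(0, 10, 0.05)
        f = np.ones(t.size)
        f[5] = np.nan
        rec = PhotometryRecording(t=t, f465=f, f405=np.ones(t.size))
        with pytest.raises(ValueError, match="non-finite"):
            preprocess_dff(rec)


class TestDetector:
    def test_flat_trace_yields_no_events(self):
        series = detect_transients(make_trace(np.zeros(2000)))
        assert series.event_times_s.size == 0

    def test_single_clean_excursion_detected_once_with_amplitude(self):
        series = detect_transients(single_bump_trace(5.0))
        assert series.event_times_s.size == 1
        assert series.event_amplitudes_pct[0] == pytest.approx(5.0, abs=0.05)

    def test_detection_is_step_at_threshold(self):
        # strictly-greater criterion: 2.0 is out, 2.0+eps is in
        for amp, expect in [(1.5, 0), (2.0, 0), (2.001, 1), (3.0, 1)]:
            series = detect_transients(single_bump_trace(amp))
            assert series.event_times_s.size == expect, amp

    def test_sub_threshold_never_detected_either_envelope(self):
        for method in ("interp", "sliding"):
            opts = PhotometryOptions(envelope=method)
            assert detect_transients(single_bump_trace(1.9),
                                     options=opts).event_times_s.size == 0
            assert detect_transients(single_bump_trace(4.0),
                                     options=opts).event_times_s.size == 1

    def test_sensitivity_and_fdr_at_high_snr(self, isolated_event_session):
        cfg, rec, truth = isolated_event_session
        series = detect_transients(preprocess_dff(rec))
        _, sens, fdr = match_events(series.event_times_s,
                                    truth.transient_times_s, tol_s=1.0)
        assert sens >= 0.95
        assert fdr <= 0.05

    def test_scale_invariance_of_transient_series(self,
                                                  default_photometry_session):
        _, rec, _ = default_photometry_session
        s1 = detect_transients(preprocess_dff(rec))
        scaled = PhotometryRecording(t=rec.t, f465=rec.f465 * 7.3,
                                     f405=rec.f405 * 7.3, meta=rec.meta)
        s2 = detect_transients(preprocess_dff(scaled))
        assert np.allclose(s1.event_times_s, s2.event_times_s)
        assert np.allclose(s1.event_amplitudes_pct, s2.event_amplitudes_pct,
                           rtol=1e-6)

    def test_count_conservation_in_bins(self, default_photometry_session):
        _, rec, _ = default_photometry_session
        s = detect_transients(preprocess_dff(rec))
        assert int(s.binned_rate.sum()) == s.event_times_s.size
        assert np.allclose(s.delta_rate + s.baseline_rate, s.binned_rate)

    def test_nan_trace_rejected(self):
        trace = make_trace(np.zeros(100))
        trace.dff[3] = np.nan
        with pytest.raises(ValueError):
            detect_transients(trace)

    def test_short_trace_empty_not_error(self):
        series = detect_transients(make_trace([0.0, 1.0]))
        assert series.event_times_s.size == 0


class TestSessionMetrics:
    @staticmethod
    def series_from_delta(delta, baseline_rate=0.0, start_min=-30):
        starts = np.arange(start_min, start_min + len(delta), dtype=float)
        rate = np.asarray(delta, float) + baseline_rate
        return TransientSeries(event_times_s=np.empty(0),
                               event_amplitudes_pct=np.empty(0),
                               bin_start_min=starts, binned_rate=rate,
                               baseline_rate=baseline_rate,
                               delta_rate=np.asarray(delta, float))

    def test_zero_delta_gives_zero_aucs(self):
        s = self.series_from_delta(np.zeros(150))
        m = session_metrics(s)
        assert m.auc_onset == 0.0 and m.auc_offset == 0.0

    def test_constant_delta_rectangle_integral(self):
        # constant 3/min for the whole session: onset AUC = 3 * 20 = 60
        s = self.series_from_delta(np.full(150, 3.0))
        m = session_metrics(s)
        assert m.auc_onset == pytest.approx(60.0)
        assert m.auc_offset == pytest.approx(180.0)

    def test_auc_additive_over_partition(self):
        rng = np.random.default_rng(3)
        delta = rng.normal(0, 2, 150)
        s = self.series_from_delta(delta)
        total = 0.0
        for win in [(0, 20), (20, 30), (30, 90), (90, 120)]:
            total += session_metrics(
                s, PhotometryOptions(onset_window_min=win)).auc_onset
        full = session_metrics(
            s, PhotometryOptions(onset_window_min=(0, 120))).auc_onset
        assert total == pytest.approx(full)

    def test_auc_linear_in_delta(self):
        rng = np.random.default_rng(4)
        d1, d2 = rng.normal(0, 1, 150), rng.normal(0, 1, 150)
        m1 = session_metrics(self.series_from_delta(d1))
        m2 = session_metrics(self.series_from_delta(d2))
        m12 = session_metrics(self.series_from_delta(d1 + d2))
        assert m12.auc_onset == pytest.approx(m1.auc_onset + m2.auc_onset)

    def test_window_outside_session_raises(self):
        s = self.series_from_delta(np.zeros(60))   # covers [-30, 30) min
        with pytest.raises(ValueError, match="window"):
            session_metrics(s, PhotometryOptions(offset_window_min=(30, 90)))

    def test_time_to_baseline_monotone_in_decay_tau(self):
        # programmed (noise-free) response curves: slower decay must never
        # shorten the reported return-to-baseline time
        taus = [5.0, 10.0, 15.0, 20.0]
        times = []
        starts = np.arange(-30, 120, dtype=float)
        for tau in taus:
            prof = ResponseProfile(latency_min=1.0, rise_tau_min=2.0,
                                   plateau_gain=6.0, decay_tau_min=tau)
            delta = prof.value(starts + 0.5)
            delta[delta < 0.25] = 0.0      # resolution floor of a rate series
            m = session_metrics(self.series_from_delta(delta))
            assert not m.censored
            times.append(m.time_to_baseline)
        assert all(a < b for a, b in zip(times, times[1:]))

    def test_censored_when_no_return(self):
        delta = np.concatenate([np.zeros(30), np.full(120, 5.0)])
        m = session_metrics(self.series_from_delta(delta))
        assert m.censored
        assert m.time_to_baseline == pytest.approx(120.0)

    def test_delta_rate_recovery_across_seeds(self):
        # detection-based mean delta over a sustained plateau vs programmed
        # increment, averaged across seeds, within 3 sigma (Poisson)
        base, gain = 0.25, 1.0
        n_seeds = 50
        p = PhotometryParams(
            session_minutes=70.0, transient_rate_baseline_per_min=base,
            amplitude_mean_pct=8.0,
            response=ResponseProfile(latency_min=0.0, rise_tau_min=0.0,
                                     plateau_gain=gain,
                                     decay_tau_min=float("inf")))
        deltas = []
        for seed in range(n_seeds):
            rec, _ = lq.gen_photometry_session(
                SimConfig(seed=seed, photometry=p))
            s = detect_transients(preprocess_dff(rec))
            sel = s.bin_start_min >= 0
            deltas.append(s.delta_rate[sel].mean())
        # per-session variance of the delta estimate (Poisson bins)
        var = (base + gain) / 40 + base / 30
        se = np.sqrt(var / n_seeds)
        assert abs(np.mean(deltas) - gain) < 3 * se

    def test_peak_dff_for_binned_sensor_sessions(self):
        starts = np.arange(-30, 120, dtype=float)
        vals = np.zeros(starts.size)
        vals[starts >= 0] = 4.0
        vals[60] = 9.0
        m = session_metrics((starts, vals))
        assert m.peak_dff == pytest.approx(9.0)
        assert m.auc_onset == pytest.approx(80.0)

    def test_bin_dff_means(self):
        t = np.arange(0.0, 120.0, 0.05)
        trace = DffTrace(t=t, dff=np.where(t < 60.0, 1.0, 3.0))
        starts, vals = bin_dff(trace)
        assert vals[0] == pytest.approx(1.0)
        assert vals[1] == pytest.approx(3.0)
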
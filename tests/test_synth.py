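"""Generator contracts: determinism, ground-truth consistency, and
statistical calibration against the programmed processes."""

import numpy as np
import pytest

import lidquant as lq
from lidquant.synth import (AimParams, CurrentClampParams, MiniParams,
                            PhotometryParams, ResponseProfile, SimConfig,
                            SpikeParams, dense_schedule_minutes)


def small_photometry(seed=0, **kw):
    p = PhotometryParams(sampling_rate_hz=5.0, **kw)
    return SimConfig(seed=seed, photometry=p)


class TestDeterminism:
    def test_photometry_bit_identical(self):
        cfg = small_photometry(seed=3)
        r1, t1 = lq.gen_photometry_session(cfg)
        r2, t2 = lq.gen_photometry_session(cfg)
        assert np.array_equal(r1.f465, r2.f465)
        assert np.array_equal(r1.f405, r2.f405)
        assert np.array_equal(t1.transient_times_s, t2.transient_times_s)

    def test_spike_times_bit_identical(self):
        cfg = SimConfig(seed=9)
        u1, _ = lq.gen_spike_session(cfg, 3)
        u2, _ = lq.gen_spike_session(cfg, 3)
        for a, b in zip(u1, u2):
            assert np.array_equal(a.spike_times, b.spike_times)

    def test_mini_trace_bit_identical(self):
        cfg = SimConfig(seed=2, minis=MiniParams(duration_s=30.0))
        s1, _ = lq.gen_mini_recording(cfg)
        s2, _ = lq.gen_mini_recording(cfg)
        assert np.array_equal(s1.sweeps[0].recorded, s2.sweeps[0].recorded)

    def test_different_seeds_differ(self):
        s1, _ = lq.gen_mini_recording(SimConfig(seed=0,
                                                minis=MiniParams(duration_s=10)))
        s2, _ = lq.gen_mini_recording(SimConfig(seed=1,
                                                minis=MiniParams(duration_s=10)))
        assert not np.array_equal(s1.sweeps[0].recorded, s2.sweeps[0].recorded)


class TestPhotometryGenerator:
    def test_zero_rate_process_has_no_events(self):
        cfg = small_photometry(
            transient_rate_baseline_per_min=0.0,
            response=ResponseProfile(plateau_gain=0.0))
        _, truth = lq.gen_photometry_session(cfg)
        assert truth.transient_times_s.size == 0

    def test_baseline_count_matches_poisson_statistics(self):
        # 4/min over the 30-min baseline -> 120 expected events; the mean
        # over seeds must sit within 3 sigma of the Poisson prediction
        n_seeds = 100
        counts = []
        for seed in range(n_seeds):
            cfg = small_photometry(
                seed=seed, transient_rate_baseline_per_min=4.0,
                response=ResponseProfile(plateau_gain=0.0))
            _, truth = lq.gen_photometry_session(cfg)
            counts.append(np.sum(truth.transient_times_s < 0.0))
        mean = np.mean(counts)
        se = np.sqrt(120.0 / n_seeds)
        assert abs(mean - 120.0) < 3.0 * se

    def test_events_lie_within_session_span(self):
        cfg = small_photometry(seed=5)
        rec, truth = lq.gen_photometry_session(cfg)
        assert truth.transient_times_s.min() >= rec.t[0]
        assert truth.transient_times_s.max() <= rec.t[-1]
        assert np.all(np.diff(truth.transient_times_s) > 0)

    def test_session_must_cover_baseline(self):
        with pytest.raises(ValueError, match="baseline"):
            lq.gen_photometry_session(SimConfig(
                photometry=PhotometryParams(session_minutes=20.0)))

    def test_nan_parameter_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            lq.gen_photometry_session(SimConfig(
                photometry=PhotometryParams(noise_sd_465=float("nan"))))


class TestSpikeGenerator:
    def test_zero_modulation_labels_all_none(self):
        sp = SpikeParams(response=ResponseProfile(plateau_gain=0.0),
                         class_probs=(0.0, 0.0, 1.0))
        _, truth = lq.gen_spike_session(SimConfig(seed=4, spikes=sp), 10)
        assert all(l == "none" for l in truth.unit_labels)

    def test_rate_step_recovered_within_3_sigma(self):
        # 2 Hz baseline, x3 sustained step for "increase" units
        sp = SpikeParams(baseline_rate_hz=2.0, post_minutes=40.0,
                         refractory_ms=0.0,   # exact Poisson oracle
                         response=ResponseProfile(latency_min=0.0,
                                                  rise_tau_min=0.0,
                                                  plateau_gain=4.0,
                                                  decay_tau_min=float("inf")),
                         class_probs=(1.0, 0.0, 0.0))
        ratios = []
        n_units = 60
        units, truth = lq.gen_spike_session(SimConfig(seed=8, spikes=sp),
                                            n_units)
        t_base = 30 * 60.0
        t_post = 40 * 60.0
        for u in units:
            nb = np.sum(u.spike_times < 0)
            npost = np.sum(u.spike_times >= 0)
            ratios.append((npost / t_post) / (nb / t_base))
        # error propagation: var(ratio) ~ ratio^2 (1/Npost + 1/Nbase)
        expect = 3.0
        sd = expect * np.sqrt(1 / (6 * t_post) + 1 / (2 * t_base))
        se_mean = sd / np.sqrt(n_units)
        assert abs(np.mean(ratios) - expect) < 3.0 * se_mean

    def test_refractory_period_enforced(self):
        sp = SpikeParams(baseline_rate_hz=40.0, refractory_ms=5.0,
                         post_minutes=5.0, baseline_minutes=5.0,
                         response=ResponseProfile(plateau_gain=0.0),
                         class_probs=(0.0, 0.0, 1.0))
        units, _ = lq.gen_spike_session(SimConfig(seed=1, spikes=sp), 2)
        for u in units:
            assert np.all(np.diff(u.spike_times) >= 5e-3)

    def test_unrealizable_rate_rejected(self):
        sp = SpikeParams(baseline_rate_hz=300.0, refractory_ms=5.0,
                         response=ResponseProfile(plateau_gain=0.0))
        with pytest.raises(ValueError, match="unrealizable"):
            lq.gen_spike_session(SimConfig(spikes=sp), 1)

    def test_labels_match_modulation_sign(self):
        cfg = SimConfig(seed=12, spikes=SpikeParams(post_minutes=40.0))
        units, truth = lq.gen_spike_session(cfg, 30)
        mid = np.searchsorted(truth.rate_bin_start_min, 15.0)
        for k, lab in enumerate(truth.unit_labels):
            base = truth.unit_rate_hz[k][0]
            post = truth.unit_rate_hz[k][mid]
            if lab == "increase":
                assert post > base
            elif lab == "decrease":
                assert post < base
            else:
                assert post == pytest.approx(base)


class TestAimGenerator:
    def test_zero_severity_all_zero(self):
        cfg = SimConfig(aim=AimParams(peak_total=0.0))
        tc, _ = lq.gen_aim_timecourse(cfg)
        assert np.all(tc.totals == 0)

    def test_ceiling_curve_reaches_12_with_all_segments_4(self):
        cfg = SimConfig(aim=AimParams(peak_total=12.0))
        tc, _ = lq.gen_aim_timecourse(cfg)
        peak_obs = [o for o in tc.observations if o.total == 12]
        assert peak_obs
        assert all(o.axial == o.limb == o.orolingual == 4 for o in peak_obs)

    def test_dense_schedule_has_40_observations(self):
        # every minute for 20 min, then every 5 min to 120 -> 20 + 20
        assert dense_schedule_minutes().size == 40
        tc, _ = lq.gen_aim_timecourse(SimConfig())
        assert len(tc.observations) == 40

    def test_quantization_sums_to_rounded_curve(self):
        cfg = SimConfig(seed=0, aim=AimParams(peak_total=10.0))
        tc, truth = lq.gen_aim_timecourse(cfg)
        curve = np.interp(tc.t_min, truth.aim_curve_min,
                          truth.aim_curve_total)
        assert np.array_equal(tc.totals, np.round(curve))

    def test_overlong_schedule_rejected(self):
        with pytest.raises(ValueError, match="session"):
            lq.gen_aim_timecourse(SimConfig(
                aim=AimParams(session_minutes=60.0)))


class TestCurrentClampGenerator:
    def test_all_subthreshold_grid_never_spikes(self):
        cc = CurrentClampParams(step_grid_pa=(-100, -50, 50, 100),
                                true_rheobase_pa=250.0)
        sweeps, truth = lq.gen_current_clamp_set(SimConfig(current_clamp=cc))
        assert all(v == 0 for v in truth.spike_counts_per_step.values())

    def test_first_spiking_step_is_programmed_rheobase(self):
        cc = CurrentClampParams(step_grid_pa=(200, 225, 250, 275),
                                true_rheobase_pa=250.0)
        _, truth = lq.gen_current_clamp_set(SimConfig(current_clamp=cc))
        spiking = [s for s, n in truth.spike_counts_per_step.items() if n > 0]
        assert min(spiking) == 250.0

    def test_subthreshold_steady_state_is_ohmic(self):
        cc = CurrentClampParams(noise_sd_mv=0.0)
        sweeps, truth = lq.gen_current_clamp_set(SimConfig(current_clamp=cc))
        fs = sweeps.sampling_rate_hz
        n_pre = int(round(cc.pre_ms / 1000 * fs))
        n_step = int(round(cc.step_ms / 1000 * fs))
        for sw in sweeps.sweeps:
            step = sw.command[n_pre + n_step // 2] - sw.command[0]
            if step == 0 or step >= cc.true_rheobase_pa:
                continue
            v_ss = sw.recorded[n_pre + n_step - 10]
            defl = v_ss - cc.rmp_mv
            expect = step * cc.r_in_mohm / 1000.0
            assert defl == pytest.approx(expect, rel=0.01)

    def test_inconsistent_ap_template_rejected(self):
        with pytest.raises(ValueError):
            lq.gen_current_clamp_set(SimConfig(
                current_clamp=CurrentClampParams(ap_half_width_ms=-1.0)))
        with pytest.raises(ValueError):
            lq.gen_current_clamp_set(SimConfig(
                current_clamp=CurrentClampParams(ap_peak_mv=-60.0)))


class TestMiniGenerator:
    def test_zero_rate_empty(self):
        cfg = SimConfig(minis=MiniParams(rate_hz=0.0, duration_s=30.0))
        _, truth = lq.gen_mini_recording(cfg)
        assert truth.mini_times_s.size == 0

    def test_event_count_within_poisson_3_sigma(self):
        # 2 Hz x 600 s -> 1200 expected ground-truth events
        cfg = SimConfig(seed=17, minis=MiniParams(rate_hz=2.0,
                                                  duration_s=600.0))
        _, truth = lq.gen_mini_recording(cfg)
        assert abs(truth.mini_times_s.size - 1200) < 3 * np.sqrt(1200)

    def test_bad_kinetics_rejected(self):
        with pytest.raises(ValueError, match="rise tau"):
            lq.gen_mini_recording(SimConfig(
                minis=MiniParams(rise_tau_ms=5.0, decay_tau_ms=1.0)))
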
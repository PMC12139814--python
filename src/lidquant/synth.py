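"""Seeded synthetic-session generators with known ground truth.

Every generator emulates one acquisition modality of a levodopa treatment
session in a parkinsonian mouse: two-channel fiber photometry, in vivo
single-unit spike trains, AIM dyskinesia scoring, and ex vivo patch-clamp
sweeps.  The statistical structure mirrors what the downstream quantification
assumes — shared motion artifacts across photometry channels, exponential
photobleaching, Poisson-timed calcium transients whose rate follows a drug
response profile, levodopa-modulated firing, and parametric action-potential /
mEPSC waveforms — so that detector output can be scored against exact ground
truth.

All generators are deterministic: identical configuration and seed produce
bit-identical output.  Time is expressed in seconds with t = 0 at the drug
injection; the baseline period occupies negative time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "ResponseProfile",
    "PhotometryParams",
    "SpikeParams",
    "AimParams",
    "CurrentClampParams",
    "MiniParams",
    "GirkParams",
    "SimConfig",
    "GroundTruth",
    "gen_photometry_session",
    "gen_spike_session",
    "gen_aim_timecourse",
    "gen_current_clamp_set",
    "gen_mini_recording",
    "gen_girk_trace",
    "dense_schedule_minutes",
    "sparse_schedule_minutes",
]


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResponseProfile:
    """Parametric drug-response curve.

    The modulation is zero before ``latency_min`` minutes post-injection,
    then rises with a saturating exponential (``rise_tau_min``) toward
    ``plateau_gain`` and decays back with ``decay_tau_min`` (set to ``inf``
    for a sustained plateau).  ``sign`` selects the direction: +1 for a
    D1-MSN-like increase, -1 for a D2-MSN-like decrease.

    Units of ``plateau_gain`` follow the quantity being modulated
    (transients/min for photometry, Hz for spiking).
    """

    latency_min: float = 2.0
    rise_tau_min: float = 5.0
    plateau_gain: float = 6.0
    decay_tau_min: float = 40.0
    sign: int = 1

    def validate(self) -> None:
        if not all(np.isfinite([self.latency_min, self.rise_tau_min,
                                self.plateau_gain])):
            raise ValueError("response profile parameters must be finite")
        if self.rise_tau_min < 0 or self.decay_tau_min <= 0:
            raise ValueError("response profile taus must be positive")
        if self.sign not in (-1, 1):
            raise ValueError("response profile sign must be +1 or -1")

    def value(self, t_min):
        """Signed modulation at ``t_min`` minutes post-injection."""
        t_min = np.asarray(t_min, dtype=float)
        d = t_min - self.latency_min
        active = d > 0
        d = np.where(active, d, 0.0)
        if self.rise_tau_min > 0:
            rise = 1.0 - np.exp(-d / self.rise_tau_min)
        else:
            rise = np.ones_like(d)
        if math.isfinite(self.decay_tau_min):
            decay = np.exp(-d / self.decay_tau_min)
        else:
            decay = np.ones_like(d)
        out = self.sign * self.plateau_gain * rise * decay
        return np.where(active, out, 0.0)


@dataclass(frozen=True)
class PhotometryParams:
    """Two-channel photometry session parameters.

    Fluorescence is in arbitrary units; transient amplitudes are expressed
    as a percentage of the session's initial baseline fluorescence so the
    detector's percent-dF/F criterion applies directly.
    """

    sampling_rate_hz: float = 20.0
    session_minutes: float = 150.0
    baseline_minutes: float = 30.0
    transient_rate_baseline_per_min: float = 4.0
    response: ResponseProfile = field(default_factory=ResponseProfile)
    amplitude_mean_pct: float = 5.0
    amplitude_sd_pct: float = 1.5
    kernel_rise_tau_s: float = 0.2       # GCaMP6s-like fast rise
    kernel_decay_tau_s: float = 1.5      # slow decay
    f0_465: float = 100.0
    f0_405: float = 80.0
    bleach_tau_465_min: float = 400.0
    bleach_tau_405_min: float = 600.0
    motion_sd: float = 0.005          # fractional (multiplicative mode)
    motion_corr_time_s: float = 0.3
    motion_mode: str = "multiplicative"   # or "additive" (a.u. sd)
    motion_gain_465: float = 1.0
    motion_gain_405: float = 1.0
    noise_sd_465: float = 0.3
    noise_sd_405: float = 0.3
    indicator: str = "GCaMP6s"
    cell_class: str = "D1"


@dataclass(frozen=True)
class SpikeParams:
    """In vivo single-unit session parameters.

    Sessions span ``baseline_minutes`` before injection and
    ``post_minutes`` after, matching a 30-minute baseline followed by at
    least 80 minutes of recording.  Waveform feature pairs
    (peak-to-valley, peak width; both ms) are drawn from MSN-like or
    interneuron-like normal distributions and the drawn class is recorded
    as ground truth.
    """

    baseline_minutes: float = 30.0
    post_minutes: float = 80.0
    baseline_rate_hz: float = 3.0
    response: ResponseProfile = field(
        default_factory=lambda: ResponseProfile(plateau_gain=4.0))
    refractory_ms: float = 2.0
    class_probs: tuple = (0.45, 0.35, 0.20)   # increase, decrease, none
    interneuron_prob: float = 0.0
    msn_peak_to_valley_ms: tuple = (0.55, 0.05)
    msn_peak_width_ms: tuple = (0.20, 0.03)
    int_peak_to_valley_ms: tuple = (0.15, 0.02)
    int_peak_width_ms: tuple = (0.10, 0.02)


@dataclass(frozen=True)
class AimParams:
    """Programmed dyskinesia severity curve.

    The continuous severity curve is a rise-and-decay shape rescaled so its
    maximum equals ``peak_total`` (capped at the 12-point ceiling of the AIM
    scale), sampled on the declared scoring schedule and quantized into the
    three body-segment scores.
    """

    peak_total: float = 9.0
    onset_latency_min: float = 5.0
    rise_tau_min: float = 5.0
    offset_tau_min: float = 30.0
    schedule: str = "dense"      # dense | sparse
    session_minutes: float = 120.0


@dataclass(frozen=True)
class CurrentClampParams:
    """Current-clamp excitability sweep set.

    Voltages in mV, currents in pA, input resistance in MOhm.  Action
    potentials are piecewise-linear templates realizing the configured
    threshold, peak, half-width, and afterhyperpolarization exactly, so the
    feature extractor can be scored against them.
    """

    step_grid_pa: tuple = tuple(range(-200, 501, 50))
    true_rheobase_pa: float = 250.0
    rmp_mv: float = -80.0
    r_in_mohm: float = 100.0
    tau_m_ms: float = 15.0
    ap_threshold_mv: float = -45.0
    ap_peak_mv: float = 30.0
    ap_half_width_ms: float = 1.2
    ahp_mv: float = 12.0
    rate_at_rheobase_hz: float = 5.0
    fi_slope_hz_per_pa: float = 0.04
    first_spike_latency_ms: float = 100.0
    sampling_rate_hz: float = 20000.0
    pre_ms: float = 200.0
    step_ms: float = 500.0
    post_ms: float = 300.0
    noise_sd_mv: float = 0.0


@dataclass(frozen=True)
class MiniParams:
    """Voltage-clamp mEPSC recording parameters (inward events, pA)."""

    rate_hz: float = 2.0
    duration_s: float = 600.0
    amp_mean_pa: float = 18.0
    amp_sd_pa: float = 5.0
    amp_min_pa: float = 5.0
    rise_tau_ms: float = 0.5
    decay_tau_ms: float = 4.0
    noise_sd_pa: float = 1.5
    holding_pa: float = -20.0
    sampling_rate_hz: float = 10000.0


@dataclass(frozen=True)
class GirkParams:
    """Dopamine-evoked GIRK current trace: two successive outward plateaus
    (1 uM then saturating 100 uM dopamine) on a noisy holding current."""

    i_1um_pa: float = 60.0
    i_100um_pa: float = 120.0
    noise_sd_pa: float = 2.0
    onset_tau_s: float = 10.0
    baseline_s: float = 60.0
    apply_s: float = 180.0
    wash_s: float = 180.0
    sampling_rate_hz: float = 100.0

    # protocol landmarks (seconds from trace start)
    @property
    def t_1um_on(self) -> float:
        return self.baseline_s

    @property
    def t_1um_off(self) -> float:
        return self.baseline_s + self.apply_s

    @property
    def t_100um_on(self) -> float:
        return self.t_1um_off + self.wash_s

    @property
    def t_100um_off(self) -> float:
        return self.t_100um_on + self.apply_s

    def baseline_window(self) -> tuple:
        return (self.baseline_s * 0.1, self.baseline_s * 0.9)

    def plateau_window_1um(self) -> tuple:
        return (self.t_1um_off - 50.0, self.t_1um_off - 5.0)

    def plateau_window_100um(self) -> tuple:
        return (self.t_100um_off - 50.0, self.t_100um_off - 5.0)


@dataclass(frozen=True)
class SimConfig:
    """Complete simulation configuration for one synthetic subject/session."""

    seed: int = 0
    photometry: PhotometryParams = field(default_factory=PhotometryParams)
    spikes: SpikeParams = field(default_factory=SpikeParams)
    aim: AimParams = field(default_factory=AimParams)
    current_clamp: CurrentClampParams = field(
        default_factory=CurrentClampParams)
    minis: MiniParams = field(default_factory=MiniParams)
    girk: GirkParams = field(default_factory=GirkParams)

    def to_dict(self) -> dict:
        return asdict(self)

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))


@dataclass
class GroundTruth:
    """Programmed truth for a generated session; only the fields relevant
    to the producing generator are populated."""

    transient_times_s: np.ndarray | None = None
    transient_amplitudes_pct: np.ndarray | None = None
    rate_bin_start_min: np.ndarray | None = None
    rate_per_min: np.ndarray | None = None          # programmed transient rate
    bleach_tau_465_min: float | None = None
    unit_labels: list | None = None                 # increase | decrease | none
    unit_cell_types: list | None = None             # msn | interneuron
    unit_rate_hz: np.ndarray | None = None          # programmed rate per 1-min bin
    aim_curve_min: np.ndarray | None = None
    aim_curve_total: np.ndarray | None = None       # continuous severity curve
    rheobase_pa: float | None = None
    ap_threshold_mv: float | None = None
    ap_peak_mv: float | None = None
    ap_half_width_ms: float | None = None
    ahp_mv: float | None = None
    rmp_mv: float | None = None
    r_in_mohm: float | None = None
    spike_counts_per_step: dict | None = None
    mini_times_s: np.ndarray | None = None
    mini_amplitudes_pa: np.ndarray | None = None
    girk_i_1um_pa: float | None = None
    girk_i_100um_pa: float | None = None


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------

def _inhomogeneous_poisson(rng, rate_fn, t0: float, t1: float,
                           rate_max: float) -> np.ndarray:
    """Event times of an inhomogeneous Poisson process on [t0, t1) by
    thinning a homogeneous process at ``rate_max`` (events/s)."""
    if rate_max <= 0:
        return np.empty(0)
    n = rng.poisson(rate_max * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, n))
    keep = rng.uniform(0.0, rate_max, n) < rate_fn(cand)
    return cand[keep]


def _enforce_refractory(times: np.ndarray, refractory_s: float) -> np.ndarray:
    """Greedy dead-time: drop any spike closer than ``refractory_s`` to the
    previously kept spike.  Vectorized passes; each pass removes the first
    offender of every violation run, which reproduces the sequential greedy
    result."""
    t = times
    while t.size > 1:
        bad = np.nonzero(np.diff(t) < refractory_s)[0]
        if bad.size == 0:
            break
        first_in_run = bad[np.concatenate(([True], np.diff(bad) > 1))]
        t = np.delete(t, first_in_run + 1)
    return t


def _ou_process(rng, n: int, dt: float, sd: float, tau_s: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck noise (shared motion artifact)."""
    if sd <= 0 or n == 0:
        return np.zeros(n)
    a = math.exp(-dt / tau_s)
    white = rng.standard_normal(n)
    b = sd * math.sqrt(1.0 - a * a)
    x0 = sd * rng.standard_normal()   # stationary start
    x, _ = lfilter([b], [1.0, -a], white, zi=np.array([a * x0]))
    return x


def dense_schedule_minutes() -> np.ndarray:
    """Scoring schedule used for in vivo sessions: every minute for the
    first 20 minutes post-injection, then every 5 minutes to 120."""
    return np.concatenate([np.arange(1, 21), np.arange(25, 121, 5)]).astype(float)


def sparse_schedule_minutes() -> np.ndarray:
    """Every 20 minutes over a 2-hour session (ex vivo cohorts)."""
    return np.arange(20, 121, 20).astype(float)


# ---------------------------------------------------------------------------
# Photometry
# ---------------------------------------------------------------------------

def gen_photometry_session(config: SimConfig):
    """Simulate a two-channel photometry session.

    The 465 nm channel carries bleaching fluorescence plus calcium-transient
    kernels; the 405 nm isosbestic channel carries only its own bleach and the
    shared motion artifact.  Transient times follow an inhomogeneous Poisson
    process whose rate is the baseline rate plus the signed drug-response
    profile, clipped at zero.

    Returns ``(PhotometryRecording, GroundTruth)``.
    """
    from .photometry import PhotometryRecording  # local import to avoid cycle

    p = config.photometry
    _check_finite_params(asdict(p), "photometry")
    if p.session_minutes <= p.baseline_minutes:
        raise ValueError(
            "session_minutes (%g) must exceed baseline_minutes (%g): the "
            "session must cover both baseline and post-injection windows"
            % (p.session_minutes, p.baseline_minutes))
    p.response.validate()

    rng = np.random.default_rng(config.seed)
    fs = p.sampling_rate_hz
    dt = 1.0 / fs
    t0 = -p.baseline_minutes * 60.0
    t1 = (p.session_minutes - p.baseline_minutes) * 60.0
    n = int(round((t1 - t0) * fs))
    t = t0 + np.arange(n) * dt

    # shared artifact and per-channel noise
    motion = _ou_process(rng, n, dt, p.motion_sd, p.motion_corr_time_s)
    noise465 = rng.normal(0.0, p.noise_sd_465, n) if p.noise_sd_465 > 0 else 0.0
    noise405 = rng.normal(0.0, p.noise_sd_405, n) if p.noise_sd_405 > 0 else 0.0

    # transient times: rate in events/s = (baseline + response)/60, >= 0
    base = p.transient_rate_baseline_per_min

    def rate_per_s(ts):
        return np.clip(base + p.response.value(ts / 60.0), 0.0, None) / 60.0

    lam_max = (base + abs(p.response.plateau_gain)) / 60.0
    ev_times = _inhomogeneous_poisson(rng, rate_per_s, t0, t1, lam_max)
    amps = rng.normal(p.amplitude_mean_pct, p.amplitude_sd_pct, ev_times.size)
    amps = np.clip(amps, 0.2 * p.amplitude_mean_pct if amps.size else 0.0, None)

    # difference-of-exponentials transient kernel, unit peak
    signal = np.full(n, p.f0_465)
    if ev_times.size:
        kt = np.arange(0.0, 8.0 * p.kernel_decay_tau_s, dt)
        kern = np.exp(-kt / p.kernel_decay_tau_s) - np.exp(-kt / p.kernel_rise_tau_s)
        peak = kern.max()
        if peak > 0:
            kern /= peak
        idx = np.round((ev_times - t0) * fs).astype(int)
        for i, a in zip(idx, amps):
            hi = min(i + kern.size, n)
            if hi > i:
                signal[i:hi] += (a / 100.0) * p.f0_465 * kern[: hi - i]

    bleach465 = np.exp(-(t - t0) / (p.bleach_tau_465_min * 60.0))
    bleach405 = np.exp(-(t - t0) / (p.bleach_tau_405_min * 60.0))
    if p.motion_mode == "multiplicative":
        # fiber-coupling fluctuations scale all collected light
        f465 = bleach465 * signal * (1.0 + p.motion_gain_465 * motion) \
            + noise465
        f405 = bleach405 * p.f0_405 * (1.0 + p.motion_gain_405 * motion) \
            + noise405
    elif p.motion_mode == "additive":
        f465 = bleach465 * signal + p.motion_gain_465 * motion + noise465
        f405 = bleach405 * p.f0_405 + p.motion_gain_405 * motion + noise405
    else:
        raise ValueError(f"unknown motion_mode {p.motion_mode!r}")

    rec = PhotometryRecording(
        t=t, f465=f465, f405=f405,
        meta={"indicator": p.indicator, "cell_class": p.cell_class,
              "treatment_timepoint": "day1", "subject": f"sim{config.seed}"})

    bin_start = np.arange(-p.baseline_minutes,
                          p.session_minutes - p.baseline_minutes)
    truth = GroundTruth(
        transient_times_s=ev_times,
        transient_amplitudes_pct=amps,
        rate_bin_start_min=bin_start,
        rate_per_min=np.clip(base + p.response.value(bin_start + 0.5), 0, None),
        bleach_tau_465_min=p.bleach_tau_465_min,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------

def gen_spike_session(config: SimConfig, n_units: int):
    """Simulate ``n_units`` single units for one treatment session.

    Each unit is an inhomogeneous Poisson train with an absolute refractory
    period.  The response class (increase / decrease / none) is drawn from
    ``class_probs`` and realized by adding the signed response profile to the
    baseline rate; the drawn label and the programmed per-minute rate are
    recorded as ground truth.  Waveform features come from MSN-like or
    interneuron-like distributions.

    Returns ``(list[UnitRecording], GroundTruth)``.
    """
    from .units import UnitRecording

    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    sp = config.spikes
    _check_finite_params(asdict(sp), "spikes")
    sp.response.validate()
    refr_s = sp.refractory_ms / 1000.0
    peak_rate = sp.baseline_rate_hz + abs(sp.response.plateau_gain)
    if peak_rate > 0 and refr_s >= 1.0 / peak_rate:
        raise ValueError(
            "refractory period (%g ms) is not shorter than the mean ISI at "
            "the peak rate (%g Hz): the requested rate is unrealizable"
            % (sp.refractory_ms, peak_rate))

    rng = np.random.default_rng(config.seed)
    t0 = -sp.baseline_minutes * 60.0
    t1 = sp.post_minutes * 60.0
    labels_pool = np.array(["increase", "decrease", "none"])
    probs = np.asarray(sp.class_probs, dtype=float)
    probs = probs / probs.sum()

    units, labels, cell_types = [], [], []
    bin_start = np.arange(-sp.baseline_minutes, sp.post_minutes)
    rate_profiles = np.empty((n_units, bin_start.size))
    for k in range(n_units):
        label = str(rng.choice(labels_pool, p=probs))
        sign = {"increase": 1, "decrease": -1, "none": 0}[label]
        prof = replace(sp.response, sign=sign if sign else 1,
                       plateau_gain=sp.response.plateau_gain if sign else 0.0)

        def rate_fn(ts, _p=prof):
            return np.clip(sp.baseline_rate_hz + _p.value(ts / 60.0), 0.0, None)

        spikes = _inhomogeneous_poisson(rng, rate_fn, t0, t1, peak_rate)
        spikes = _enforce_refractory(spikes, refr_s)

        is_int = rng.uniform() < sp.interneuron_prob
        p2v = rng.normal(*(sp.int_peak_to_valley_ms if is_int
                           else sp.msn_peak_to_valley_ms))
        pw = rng.normal(*(sp.int_peak_width_ms if is_int
                          else sp.msn_peak_width_ms))
        units.append(UnitRecording(
            spike_times=spikes,
            peak_to_valley_ms=max(p2v, 0.01),
            peak_width_ms=max(pw, 0.01),
            unit_id=f"u{k:04d}", subject=f"sim{config.seed}",
            treatment_timepoint="day1"))
        labels.append(label)
        cell_types.append("interneuron" if is_int else "msn")
        rate_profiles[k] = rate_fn(60.0 * (bin_start + 0.5))

    truth = GroundTruth(unit_labels=labels, unit_cell_types=cell_types,
                        rate_bin_start_min=bin_start,
                        unit_rate_hz=rate_profiles)
    return units, truth


# ---------------------------------------------------------------------------
# AIM timecourse
# ---------------------------------------------------------------------------

def _aim_curve(aim: AimParams, t_min: np.ndarray) -> np.ndarray:
    """Continuous programmed severity, rescaled so max == peak_total."""
    prof = ResponseProfile(latency_min=aim.onset_latency_min,
                           rise_tau_min=aim.rise_tau_min,
                           plateau_gain=1.0,
                           decay_tau_min=aim.offset_tau_min, sign=1)
    fine = np.arange(0.0, aim.session_minutes + 0.05, 0.1)
    peak = prof.value(fine).max()
    if peak <= 0 or aim.peak_total <= 0:
        return np.zeros_like(np.asarray(t_min, dtype=float))
    return aim.peak_total * prof.value(t_min) / peak


def _quantize_total(total: float) -> tuple:
    """Partition a continuous total into (axial, limb, orolingual) scores in
    {0..4} summing to round(total), remainder points assigned in the fixed
    priority order axial > limb > orolingual."""
    tot = int(np.clip(round(total), 0, 12))
    base = tot // 3
    rem = tot % 3
    seg = [base, base, base]
    for i in range(rem):
        seg[i] += 1
    return tuple(seg)


def gen_aim_timecourse(config: SimConfig):
    """Sample the programmed severity curve on the scoring schedule and
    quantize it into per-segment AIM scores.

    Returns ``(AimTimecourse, GroundTruth)``; the ground truth keeps the
    continuous curve on a 0.1-minute grid.
    """
    from .behavior import AimObservation, AimTimecourse

    aim = config.aim
    if aim.peak_total > 12:
        raise ValueError("peak_total exceeds the 12-point AIM ceiling")
    sched = (dense_schedule_minutes() if aim.schedule == "dense"
             else sparse_schedule_minutes())
    if sched[-1] > aim.session_minutes + 1e-9:
        raise ValueError("scoring schedule extends past the session length")

    totals = _aim_curve(aim, sched)
    obs = []
    for tm, tot in zip(sched, totals):
        a, l, o = _quantize_total(tot)
        obs.append(AimObservation(t_min=float(tm), axial=a, limb=l,
                                  orolingual=o))
    fine = np.arange(0.0, aim.session_minutes + 0.05, 0.1)
    truth = GroundTruth(aim_curve_min=fine, aim_curve_total=_aim_curve(aim, fine))
    return AimTimecourse(observations=obs, schedule=aim.schedule), truth


# ---------------------------------------------------------------------------
# Current-clamp sweeps
# ---------------------------------------------------------------------------

def _ap_template(cc: CurrentClampParams, fs: float):
    """Piecewise-linear AP template sampled at ``fs``, starting at threshold.

    Linear rise threshold->peak over ``hw`` ms, linear fall peak->AHP trough
    over ``hw*(A+ahp)/A`` ms (so the width at half amplitude between
    threshold and peak equals ``hw`` exactly), then a 5 ms hold at the trough
    so the AHP minimum is realized inside the analysis window.
    """
    A = cc.ap_peak_mv - cc.ap_threshold_mv
    if A <= 0:
        raise ValueError("AP peak must lie above threshold")
    if cc.ap_half_width_ms <= 0:
        raise ValueError("AP half-width must be positive")
    if cc.ahp_mv < 0:
        raise ValueError("AHP magnitude must be non-negative (trough below "
                         "threshold)")
    tr = cc.ap_half_width_ms / 1000.0
    tf = tr * (A + cc.ahp_mv) / A
    hold = 5e-3
    t_rise = np.arange(0.0, tr, 1.0 / fs)
    t_fall = np.arange(0.0, tf, 1.0 / fs)
    t_hold = np.arange(0.0, hold, 1.0 / fs)
    v = np.concatenate([
        cc.ap_threshold_mv + A * t_rise / tr,
        cc.ap_peak_mv - (A + cc.ahp_mv) * t_fall / tf,
        np.full(t_hold.size, cc.ap_threshold_mv - cc.ahp_mv),
    ])
    return v


def gen_current_clamp_set(config: SimConfig):
    """Simulate a family of current-step sweeps for one cell.

    Sub-rheobase steps produce a leaky-RC voltage response whose steady
    state is Ohmic (I x R_in); steps at or above the programmed rheobase
    produce regular spiking built from the parametric AP template, with the
    inter-spike membrane potential relaxing toward threshold.

    Returns ``(SweepSet, GroundTruth)``.
    """
    from .slice_ephys import Sweep, SweepSet

    cc = config.current_clamp
    steps = np.asarray(cc.step_grid_pa, dtype=float)
    if steps.size < 2 or np.any(np.diff(steps) <= 0):
        raise ValueError("step grid must be strictly increasing")
    _ap_template(cc, cc.sampling_rate_hz)   # validates the template

    rng = np.random.default_rng(config.seed)
    fs = cc.sampling_rate_hz
    dt = 1.0 / fs
    n_pre = int(round(cc.pre_ms / 1000.0 * fs))
    n_step = int(round(cc.step_ms / 1000.0 * fs))
    n_post = int(round(cc.post_ms / 1000.0 * fs))
    n = n_pre + n_step + n_post
    t = np.arange(n) * dt
    tau = cc.tau_m_ms / 1000.0
    template = _ap_template(cc, fs)

    sweeps = []
    counts = {}
    for I in steps:
        i_cmd = np.zeros(n)
        i_cmd[n_pre:n_pre + n_step] = I
        v = np.full(n, cc.rmp_mv)
        tt = np.arange(n_step) * dt
        spiking = I >= cc.true_rheobase_pa and I > 0
        if spiking:
            # RC relaxation toward threshold, regular APs on top
            v_seg = cc.ap_threshold_mv - (cc.ap_threshold_mv - cc.rmp_mv) \
                * np.exp(-tt / tau)
            rate = cc.rate_at_rheobase_hz \
                + cc.fi_slope_hz_per_pa * (I - cc.true_rheobase_pa)
            isi = 1.0 / rate
            t_sp = cc.first_spike_latency_ms / 1000.0
            spike_times = []
            while t_sp < cc.step_ms / 1000.0 - (template.size + 1) * dt:
                spike_times.append(t_sp)
                t_sp += isi
            for s in spike_times:
                k0 = int(round(s * fs))
                k1 = min(k0 + template.size, n_step)
                v_seg[k0:k1] = template[: k1 - k0]
                # relax from the AHP trough back toward threshold
                if k1 < n_step:
                    rec_t = np.arange(n_step - k1) * dt
                    v_seg[k1:] = cc.ap_threshold_mv - cc.ahp_mv \
                        * np.exp(-rec_t / tau)
            counts[float(I)] = len(spike_times)
        else:
            defl = I * cc.r_in_mohm / 1000.0   # pA * MOhm = uV -> mV
            v_seg = cc.rmp_mv + defl * (1.0 - np.exp(-tt / tau))
            counts[float(I)] = 0
        v[n_pre:n_pre + n_step] = v_seg
        v_end = v[n_pre + n_step - 1]
        v[n_pre + n_step:] = cc.rmp_mv + (v_end - cc.rmp_mv) \
            * np.exp(-np.arange(n_post) * dt / tau)
        if cc.noise_sd_mv > 0:
            v = v + rng.normal(0.0, cc.noise_sd_mv, n)
        sweeps.append(Sweep(t=t, command=i_cmd, recorded=v))

    sweep_set = SweepSet(sweeps=sweeps, mode="current_clamp",
                         sampling_rate_hz=fs)
    truth = GroundTruth(
        rheobase_pa=cc.true_rheobase_pa if counts and
        max(counts.values()) > 0 else None,
        ap_threshold_mv=cc.ap_threshold_mv, ap_peak_mv=cc.ap_peak_mv,
        ap_half_width_ms=cc.ap_half_width_ms, ahp_mv=cc.ahp_mv,
        rmp_mv=cc.rmp_mv, r_in_mohm=cc.r_in_mohm,
        spike_counts_per_step=counts)
    return sweep_set, truth


# ---------------------------------------------------------------------------
# mEPSC recording
# ---------------------------------------------------------------------------

def gen_mini_recording(config: SimConfig):
    """Simulate a voltage-clamp mEPSC recording.

    Poisson-timed biexponential inward (negative) events of drawn amplitudes
    ride on a noisy holding current.  Returns ``(SweepSet, GroundTruth)``
    with ground-truth onset times and amplitudes.
    """
    from .slice_ephys import Sweep, SweepSet

    mp = config.minis
    if mp.rate_hz < 0:
        raise ValueError("mini rate must be non-negative")
    if mp.decay_tau_ms <= mp.rise_tau_ms or mp.rise_tau_ms <= 0:
        raise ValueError("mini kinetics must satisfy 0 < rise tau < decay tau")

    rng = np.random.default_rng(config.seed)
    fs = mp.sampling_rate_hz
    dt = 1.0 / fs
    n = int(round(mp.duration_s * fs))
    t = np.arange(n) * dt
    trace = np.full(n, mp.holding_pa)
    if mp.noise_sd_pa > 0:
        trace += rng.normal(0.0, mp.noise_sd_pa, n)

    n_ev = rng.poisson(mp.rate_hz * mp.duration_s)
    ev_times = np.sort(rng.uniform(0.0, mp.duration_s, n_ev))
    amps = np.clip(rng.normal(mp.amp_mean_pa, mp.amp_sd_pa, n_ev),
                   mp.amp_min_pa, None)

    if n_ev:
        rise = mp.rise_tau_ms / 1000.0
        decay = mp.decay_tau_ms / 1000.0
        kt = np.arange(0.0, 8.0 * decay, dt)
        kern = np.exp(-kt / decay) - np.exp(-kt / rise)
        kern /= kern.max()
        idx = np.round(ev_times * fs).astype(int)
        for i, a in zip(idx, amps):
            hi = min(i + kern.size, n)
            if hi > i:
                trace[i:hi] -= a * kern[: hi - i]   # inward = negative

    sweep = Sweep(t=t, command=np.full(n, -70.0), recorded=trace)
    sweep_set = SweepSet(sweeps=[sweep], mode="voltage_clamp",
                         sampling_rate_hz=fs)
    truth = GroundTruth(mini_times_s=ev_times, mini_amplitudes_pa=amps)
    return sweep_set, truth


# ---------------------------------------------------------------------------
# GIRK trace
# ---------------------------------------------------------------------------

def gen_girk_trace(config: SimConfig):
    """Simulate a dopamine-evoked GIRK current trace: a 1 uM plateau, wash,
    then a saturating 100 uM plateau, with first-order onset/offset kinetics.

    Returns ``(t_s, current_pa, GroundTruth)`` plus the window boundaries in
    the ground truth amplitudes.
    """
    g = config.girk
    rng = np.random.default_rng(config.seed)
    fs = g.sampling_rate_hz
    dt = 1.0 / fs
    total = g.baseline_s + 2 * g.apply_s + 2 * g.wash_s
    n = int(round(total * fs))
    t = np.arange(n) * dt

    def plateau(t_on, t_off, amp):
        out = np.zeros(n)
        on = t >= t_on
        out[on] = amp * (1.0 - np.exp(-(t[on] - t_on) / g.onset_tau_s))
        off = t >= t_off
        out[off] = out[np.searchsorted(t, t_off)] \
            * np.exp(-(t[off] - t_off) / g.onset_tau_s)
        return out

    i1_on = g.baseline_s
    i1_off = i1_on + g.apply_s
    i100_on = i1_off + g.wash_s
    i100_off = i100_on + g.apply_s
    trace = plateau(i1_on, i1_off, g.i_1um_pa) \
        + plateau(i100_on, i100_off, g.i_100um_pa)
    if g.noise_sd_pa > 0:
        trace = trace + rng.normal(0.0, g.noise_sd_pa, n)
    truth = GroundTruth(girk_i_1um_pa=g.i_1um_pa, girk_i_100um_pa=g.i_100um_pa)
    return t, trace, truth


# ---------------------------------------------------------------------------

def _check_finite_params(d: dict, where: str) -> None:
    for key, val in d.items():
        if isinstance(val, dict):
            _check_finite_params(val, f"{where}.{key}")
        elif isinstance(val, (int, float)):
            # inf is a legal decay tau (sustained plateau); NaN never is
            if isinstance(val, float) and math.isnan(val):
                raise ValueError(f"non-finite parameter {where}.{key}")
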
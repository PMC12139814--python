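"""Ex vivo patch-clamp quantification.

Three analyses, matching whole-cell workflows on striatal medium spiny
neurons:

* ``excitability`` — current-clamp step families: spike counts and f-I
  relation, rheobase, action-potential threshold / half-width / AHP,
  resting membrane potential, and subthreshold voltage deflections;
* ``detect_minis`` — voltage-clamp mEPSC detection by smoothed-derivative
  threshold crossing, with the 500-event inclusion and truncation rules
  applied to the cumulative distributions;
* ``girk_ratio`` — dopamine-evoked GIRK current amplitudes and the
  1 uM / 100 uM ratio used as a D2-receptor sensitivity index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

__all__ = [
    "Sweep",
    "SweepSet",
    "ExcitabilityProfile",
    "MiniSummary",
    "GirkResponse",
    "ExcitabilityParams",
    "MiniDetectParams",
    "excitability",
    "detect_minis",
    "girk_ratio",
    "plateau_current",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class Sweep:
    """One sweep: time (s), command (pA in current clamp, mV in voltage
    clamp), and the recorded trace (mV or pA respectively)."""

    t: np.ndarray
    command: np.ndarray
    recorded: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.command = np.asarray(self.command, dtype=float)
        self.recorded = np.asarray(self.recorded, dtype=float)
        if not (len(self.t) == len(self.command) == len(self.recorded)):
            raise ValueError("sweep arrays must have equal length")


@dataclass
class SweepSet:
    sweeps: list
    mode: str                       # current_clamp | voltage_clamp
    sampling_rate_hz: float


@dataclass
class ExcitabilityProfile:
    """Per-cell excitability summary from a current-step family."""

    step_pa: np.ndarray
    spike_counts: np.ndarray
    mean_rate_hz: np.ndarray
    instantaneous_rate_hz: np.ndarray     # 1 / first ISI; NaN when < 2 spikes
    rheobase_pa: float                    # NaN when censored-above
    rheobase_censored: bool
    ap_threshold_mv: float
    ap_peak_mv: float
    half_width_ms: float
    ahp_mv: float                         # positive = trough below threshold
    rmp_mv: float
    deflection_mv: np.ndarray             # NaN for spiking steps
    max_rate_hz: float


@dataclass
class MiniSummary:
    """Detected mEPSC events with the fixed inclusion/truncation rules:
    a cell is included only when at least 500 events were detected, and the
    cumulative inter-event-interval and amplitude distributions are built
    from the first 500 events only."""

    event_times_s: np.ndarray
    event_amplitudes_pa: np.ndarray
    frequency_hz: float
    mean_amplitude_pa: float
    included: bool
    cumulative_iei_s: np.ndarray          # from the first min(500, n) events
    cumulative_amplitude_pa: np.ndarray


@dataclass
class GirkResponse:
    i_1um_pa: float
    i_100um_pa: float
    ratio: float                          # NaN when undefined
    defined: bool


# ---------------------------------------------------------------------------
# Excitability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExcitabilityParams:
    """Detection conventions for the current-clamp analysis.  The spike
    detection level, slope criterion, and AHP window are package
    conventions, exposed here so a processing record can cite them."""

    spike_level_mv: float = -10.0
    dvdt_threshold_mv_per_ms: float = 20.0
    ahp_window_ms: tuple = (2.0, 50.0)
    steady_state_fraction: float = 0.25


def _step_window(sweeps) -> tuple:
    """Locate the (on, off) sample indices of the command step, shared
    across the set (taken from the first sweep with a nonzero step)."""
    for sw in sweeps:
        base = sw.command[0]
        idx = np.nonzero(sw.command != base)[0]
        if idx.size:
            return int(idx[0]), int(idx[-1] + 1)
    raise ValueError("no sweep contains a command step")


def _detect_spikes(v: np.ndarray, fs: float, p: ExcitabilityParams
                   ) -> np.ndarray:
    """Indices of upward crossings of the spike level confirmed by the
    dV/dt criterion in the surrounding millisecond."""
    lvl = p.spike_level_mv
    up = np.nonzero((v[:-1] < lvl) & (v[1:] >= lvl))[0] + 1
    if up.size == 0:
        return up
    dvdt = np.gradient(v) * fs / 1000.0   # mV/ms
    half = max(int(round(1e-3 * fs)), 1)
    ok = [i for i in up
          if dvdt[max(i - half, 0): i + half + 1].max()
          >= p.dvdt_threshold_mv_per_ms]
    return np.asarray(ok, dtype=int)


def _ap_features(v: np.ndarray, fs: float, crossing: int,
                 p: ExcitabilityParams):
    """Threshold, peak, half-width, AHP of the spike at ``crossing``."""
    dvdt = np.gradient(v) * fs / 1000.0
    # AP peak: first local max at/after the crossing
    j = crossing
    while j + 1 < v.size and v[j + 1] >= v[j]:
        j += 1
    peak_idx, peak = j, v[j]
    # threshold: first sample before the peak where dV/dt reaches criterion
    back = max(peak_idx - int(round(10e-3 * fs)), 0)
    seg = dvdt[back:peak_idx + 1]
    above = np.nonzero(seg >= p.dvdt_threshold_mv_per_ms)[0]
    thr_idx = back + (above[0] if above.size else 0)
    thr = v[thr_idx]
    # half-width at the level midway between threshold and peak
    half_level = 0.5 * (thr + peak)
    i = peak_idx
    while i > thr_idx and v[i - 1] > half_level:
        i -= 1
    t_up = i - 1 + (half_level - v[i - 1]) / (v[i] - v[i - 1]) \
        if i > 0 and v[i] != v[i - 1] else float(i)
    k = peak_idx
    while k + 1 < v.size and v[k + 1] > half_level:
        k += 1
    t_dn = k + (v[k] - half_level) / (v[k] - v[k + 1]) \
        if k + 1 < v.size and v[k] != v[k + 1] else float(k)
    half_width_ms = (t_dn - t_up) / fs * 1000.0
    # AHP: threshold minus the post-peak minimum inside the AHP window
    w0 = peak_idx + int(round(p.ahp_window_ms[0] * 1e-3 * fs))
    w1 = peak_idx + int(round(p.ahp_window_ms[1] * 1e-3 * fs))
    trough = v[w0:min(w1, v.size)].min() if w0 < v.size else v[-1]
    return float(thr), float(peak), float(half_width_ms), float(thr - trough)


def excitability(sweep_set: SweepSet,
                 params: ExcitabilityParams = ExcitabilityParams()
                 ) -> ExcitabilityProfile:
    """Extract the excitability profile from a current-clamp step family.

    Rheobase is the smallest tested current evoking at least one spike
    (NaN + censored flag when no step spikes).  AP features are measured on
    the first spike of the rheobase sweep.  Subthreshold deflection is the
    steady-state minus pre-step voltage of each non-spiking step.
    """
    if sweep_set.mode != "current_clamp":
        raise ValueError("excitability requires current-clamp sweeps")
    fs = sweep_set.sampling_rate_hz
    on, off = _step_window(sweep_set.sweeps)
    step_dur_s = (off - on) / fs

    steps, counts, mean_rate, inst_rate, defl = [], [], [], [], []
    spike_idx_per_sweep = []
    rmp_vals = []
    for sw in sweep_set.sweeps:
        step_pa = float(sw.command[on:off].mean() - sw.command[0])
        v = sw.recorded
        rmp_vals.append(v[:on].mean() if on else v.mean())
        spk = _detect_spikes(v[on:off], fs, params)
        spike_idx_per_sweep.append(spk + on)
        steps.append(step_pa)
        counts.append(spk.size)
        mean_rate.append(spk.size / step_dur_s)
        if spk.size >= 2:
            inst_rate.append(fs / (spk[1] - spk[0]))
        else:
            inst_rate.append(np.nan)
        if spk.size == 0:
            n_ss = max(int(round(params.steady_state_fraction * (off - on))), 1)
            ss = v[off - n_ss:off].mean()
            defl.append(ss - v[:on].mean() if on else np.nan)
        else:
            defl.append(np.nan)

    steps = np.asarray(steps)
    counts = np.asarray(counts)
    order = np.argsort(steps)
    spiking = np.nonzero((counts[order] > 0))[0]
    if spiking.size:
        rheo_pos = order[spiking[0]]
        rheobase = float(steps[rheo_pos])
        censored = False
        first_spk = spike_idx_per_sweep[rheo_pos][0]
        thr, peak, hw, ahp = _ap_features(
            sweep_set.sweeps[rheo_pos].recorded, fs, first_spk, params)
    else:
        rheobase, censored = float("nan"), True
        thr = peak = hw = ahp = float("nan")

    return ExcitabilityProfile(
        step_pa=steps, spike_counts=counts,
        mean_rate_hz=np.asarray(mean_rate),
        instantaneous_rate_hz=np.asarray(inst_rate),
        rheobase_pa=rheobase, rheobase_censored=censored,
        ap_threshold_mv=thr, ap_peak_mv=peak, half_width_ms=hw, ahp_mv=ahp,
        rmp_mv=float(np.mean(rmp_vals)),
        deflection_mv=np.asarray(defl),
        max_rate_hz=float(np.nanmax(mean_rate) if len(mean_rate) else np.nan))


# ---------------------------------------------------------------------------
# mEPSC detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MiniDetectParams:
    """Smoothed-derivative mEPSC detector settings.

    The derivative of the lightly smoothed current trace is thresholded at
    ``k_mad`` robust standard deviations (MAD-scaled) of its noise; negative
    crossings separated by at least ``min_separation_ms`` mark event onsets.
    Amplitude is local pre-event baseline minus the event trough.
    """

    smooth_ms: float = 1.0
    k_mad: float = 5.0
    min_separation_ms: float = 5.0
    peak_search_ms: float = 10.0
    baseline_ms: float = 3.0
    inclusion_min_events: int = 500
    truncate_events: int = 500


def detect_minis(sweep_set: SweepSet,
                 params: MiniDetectParams = MiniDetectParams()) -> MiniSummary:
    """Detect inward miniature synaptic events in a voltage-clamp recording.

    Applies the fixed reporting rules: the cell is flagged ``included`` only
    if at least 500 events were detected, and the cumulative inter-event
    interval and amplitude arrays are built from the first 500 events.
    """
    if sweep_set.mode != "voltage_clamp":
        raise ValueError("mini detection requires voltage-clamp sweeps")
    sw = sweep_set.sweeps[0]
    trace = sw.recorded
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite samples")
    fs = sweep_set.sampling_rate_hz
    duration = trace.size / fs
    if duration <= 0:
        raise ValueError("zero-duration recording")

    win = max(int(round(params.smooth_ms * 1e-3 * fs)), 1)
    smooth = uniform_filter1d(trace, size=win, mode="nearest")
    d = np.diff(smooth)
    mad = np.median(np.abs(d - np.median(d))) * 1.4826
    thr = -params.k_mad * max(mad, 1e-12)
    below = d < thr
    onsets = np.nonzero(below & ~np.roll(below, 1))[0]
    onsets = onsets[onsets > 0]

    min_sep = int(round(params.min_separation_ms * 1e-3 * fs))
    kept = []
    last = -min_sep - 1
    for i in onsets:
        if i - last >= min_sep:
            kept.append(i)
            last = i
    kept = np.asarray(kept, dtype=int)

    # amplitudes on the smoothed trace: raw-trace minima ride the noise floor
    n_peak = int(round(params.peak_search_ms * 1e-3 * fs))
    n_base = int(round(params.baseline_ms * 1e-3 * fs))
    times, amps = [], []
    for i in kept:
        seg = smooth[i: min(i + n_peak, smooth.size)]
        if seg.size == 0:
            continue
        trough = seg.min()
        b0 = max(i - n_base, 0)
        base = np.median(smooth[b0:i]) if i > b0 else smooth[i]
        amp = base - trough
        if amp <= 0:
            continue
        times.append(i / fs)
        amps.append(amp)
    times = np.asarray(times)
    amps = np.asarray(amps)

    n = times.size
    k = min(params.truncate_events, n)
    first_t = times[:k]
    first_a = np.sort(amps[:k])
    iei = np.sort(np.diff(first_t)) if k > 1 else np.empty(0)
    return MiniSummary(
        event_times_s=times, event_amplitudes_pa=amps,
        frequency_hz=n / duration,
        mean_amplitude_pa=float(amps.mean()) if n else float("nan"),
        included=n >= params.inclusion_min_events,
        cumulative_iei_s=iei, cumulative_amplitude_pa=first_a)


# ---------------------------------------------------------------------------
# GIRK dopamine-response ratio
# ---------------------------------------------------------------------------

def plateau_current(t_s: np.ndarray, i_pa: np.ndarray,
                    baseline_window_s, plateau_window_s) -> float:
    """Plateau amplitude: mean current in the plateau window minus the mean
    over the pre-drug baseline window (outward positive, pA)."""
    t = np.asarray(t_s, dtype=float)
    i = np.asarray(i_pa, dtype=float)
    b = (t >= baseline_window_s[0]) & (t < baseline_window_s[1])
    p = (t >= plateau_window_s[0]) & (t < plateau_window_s[1])
    if not (b.any() and p.any()):
        raise ValueError("baseline or plateau window outside the trace")
    return float(i[p].mean() - i[b].mean())


def girk_ratio(i_1um_pa: float, i_100um_pa: float) -> GirkResponse:
    """Ratio of GIRK currents evoked by 1 uM versus saturating 100 uM
    dopamine; an index of D2-receptor sensitivity.  The ratio is undefined
    (NaN, flagged) when the saturating response is not positive."""
    if i_100um_pa <= 0:
        return GirkResponse(i_1um_pa=float(i_1um_pa),
                            i_100um_pa=float(i_100um_pa),
                            ratio=float("nan"), defined=False)
    return GirkResponse(i_1um_pa=float(i_1um_pa),
                        i_100um_pa=float(i_100um_pa),
                        ratio=float(i_1um_pa) / float(i_100um_pa),
                        defined=True)
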
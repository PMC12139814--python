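"""Fiber photometry quantification.

The processing chain mirrors standard two-channel (signal + isosbestic)
practice for bulk calcium or dopamine-sensor recordings:

1. motion correction — the 405 nm isosbestic channel is mapped onto the
   465 nm channel with a first-degree polynomial (ordinary least squares)
   and the fitted artifact is subtracted;
2. bleach normalization (calcium-indicator sessions) — a single decaying
   exponential plus offset is fit to the 465 nm signal and the corrected
   residual is divided by the fit, yielding dF/F in percent; a flat,
   artifact-free trace gives exactly 0 %.  Dopamine-sensor sessions skip
   the exponential and normalize by the pre-injection mean instead;
3. smoothing with a centered moving average;
4. transient detection on the envelope of dF/F: envelope valleys are paired
   with the next envelope peak and a pair whose valley-to-peak difference
   strictly exceeds the threshold (default 2 % dF/F) counts as one transient;
5. 1-minute binning of transient counts (or dF/F), baseline subtraction over
   the 30-minute pre-injection window, and session metrics: AUC over the
   dyskinesia onset (0-20 min) and offset (30-90 min) windows, time for the
   rate to return to baseline, and peak dF/F for dopamine-sensor sessions.

Every output is invariant to rescaling both raw channels by a common
positive factor: the regression residual and the bleach fit scale together,
so dF/F does not change.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.ndimage import uniform_filter1d, maximum_filter1d
from scipy.signal import argrelextrema

__all__ = [
    "PhotometryRecording",
    "DffTrace",
    "TransientSeries",
    "PhotometryMetrics",
    "PhotometryOptions",
    "preprocess_dff",
    "detect_transients",
    "bin_dff",
    "session_metrics",
]

BASELINE_WINDOW_MIN = (-30.0, 0.0)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class PhotometryRecording:
    """Raw two-channel recording on an injection-aligned time base.

    ``t`` is uniformly sampled time in seconds with the drug injection at
    t = 0 and the baseline period at negative times.  ``meta`` carries
    indicator, cell class, treatment timepoint, and subject id.
    """

    t: np.ndarray
    f465: np.ndarray
    f405: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.f465 = np.asarray(self.f465, dtype=float)
        self.f405 = np.asarray(self.f405, dtype=float)
        if not (len(self.t) == len(self.f465) == len(self.f405)):
            raise ValueError("t, f465, f405 must have equal length")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("time base must be strictly increasing")
            if np.ptp(dt) > 1e-6 * dt.mean():
                raise ValueError("time base must be uniform (within 1 ppm)")

    @property
    def sampling_rate_hz(self) -> float:
        return 1.0 / (self.t[1] - self.t[0])


@dataclass
class DffTrace:
    """dF/F in percent plus the processing record that reproduces it."""

    t: np.ndarray
    dff: np.ndarray
    processing: dict = field(default_factory=dict)


@dataclass
class TransientSeries:
    """Detected transients and the binned, baseline-subtracted rate series.

    Bins are half-open 1-minute intervals [k, k+1) minutes post-injection;
    ``bin_start_min`` gives each bin's left edge.  ``delta_rate`` is
    ``binned_rate`` minus the mean rate over the 30-minute baseline.
    """

    event_times_s: np.ndarray
    event_amplitudes_pct: np.ndarray
    bin_start_min: np.ndarray
    binned_rate: np.ndarray           # transients / min
    baseline_rate: float
    delta_rate: np.ndarray


@dataclass
class PhotometryMetrics:
    """Session-level photometry metrics.

    AUCs integrate the baseline-subtracted series over the dyskinesia onset
    (0-20 min) and offset (30-90 min) windows.  ``time_to_baseline`` is the
    first post-peak minute at which the series returns to (and stays at)
    baseline; ``censored`` flags sessions where it never does.  ``peak_dff``
    is populated for dopamine-sensor sessions analyzed on binned dF/F.
    """

    auc_onset: float
    auc_offset: float
    time_to_baseline: float
    censored: bool
    peak_dff: float | None = None


@dataclass(frozen=True)
class PhotometryOptions:
    """Tunable analysis parameters (every default is recorded on use)."""

    bleach_correct: bool | None = None     # None -> by indicator metadata
    smooth_window_s: float = 0.5
    envelope: str = "interp"               # interp | sliding
    sliding_window_s: float = 1.0
    threshold_pct: float = 2.0
    onset_window_min: tuple = (0.0, 20.0)
    offset_window_min: tuple = (30.0, 90.0)
    baseline_return_tol: float = 0.0
    baseline_return_bins: int = 5


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def _fit_bleach(t: np.ndarray, y: np.ndarray):
    """Least-squares fit of ``a * exp(-(t - t0)/tau) + c``; returns the
    fitted curve and parameters, or ``None`` on failure."""
    t0 = t[0]
    span = t[-1] - t0
    head = y[: max(len(y) // 20, 2)].mean()
    tail = y[-max(len(y) // 20, 2):].mean()

    def model(tt, a, tau, c):
        return a * np.exp(-(tt - t0) / tau) + c

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model, t, y,
                p0=[max(head - tail, 1e-6 * max(abs(head), 1.0)),
                    span / 3.0, tail],
                bounds=([-np.inf, span * 1e-4, -np.inf],
                        [np.inf, span * 1e4, np.inf]),
                maxfev=10000)
    except (RuntimeError, ValueError):
        return None, None
    fit = model(t, *popt)
    if not np.all(np.isfinite(fit)):
        return None, None
    return fit, {"a": float(popt[0]), "tau_s": float(popt[1]),
                 "c": float(popt[2])}


def preprocess_dff(rec: PhotometryRecording,
                   options: PhotometryOptions = PhotometryOptions()) -> DffTrace:
    """Motion-correct, bleach-normalize, and smooth a raw recording.

    Returns a :class:`DffTrace` whose ``processing`` record holds the
    isosbestic fit coefficients, bleach fit parameters (or the fallback
    used), and the smoothing window, so the trace can be reproduced from the
    raw channels.
    """
    if not (np.all(np.isfinite(rec.f465)) and np.all(np.isfinite(rec.f405))):
        raise ValueError("raw channels contain non-finite samples")
    t = rec.t
    proc: dict = {"smooth_window_s": options.smooth_window_s}

    # 1. isosbestic regression (motion correction)
    if np.ptp(rec.f405) <= 1e-12 * max(np.abs(rec.f405).max(), 1.0):
        # constant isosbestic: intercept-only fit
        slope, intercept = 0.0, float(rec.f465.mean())
        proc["isosbestic_fit"] = {"slope": slope, "intercept": intercept,
                                  "degenerate": True}
        warnings.warn("isosbestic channel is constant; intercept-only "
                      "motion fit", RuntimeWarning, stacklevel=2)
    else:
        slope, intercept = np.polyfit(rec.f405, rec.f465, 1)
        proc["isosbestic_fit"] = {"slope": float(slope),
                                  "intercept": float(intercept),
                                  "degenerate": False}
    corrected = rec.f465 - (slope * rec.f405 + intercept)

    # 2. bleach normalization: denominator from the 465 baseline trend
    scale = max(np.abs(rec.f465).max(), np.abs(rec.f405).max(), 1e-300)
    bleach = options.bleach_correct
    if bleach is None:
        bleach = str(rec.meta.get("indicator", "")).upper().startswith("GCAMP")
    f0 = None
    if bleach:
        fit, params = _fit_bleach(t, rec.f465)
        if fit is not None and np.all(fit > 1e-12 * scale):
            proc["bleach_fit"] = params
            f0 = fit
        else:
            warnings.warn("exponential bleach fit failed; linear detrend "
                          "fallback", RuntimeWarning, stacklevel=2)
            coef = np.polyfit(t, rec.f465, 1)
            trend = np.polyval(coef, t)
            proc["bleach_fit"] = {"fallback": "linear",
                                  "slope": float(coef[0]),
                                  "intercept": float(coef[1])}
            if np.all(trend > 1e-12 * scale):
                f0 = trend
    if f0 is None:
        # sensor sessions (no appreciable bleaching) or degenerate fits:
        # normalize by the pre-injection mean of the raw 465 signal
        pre = rec.f465[t < 0.0]
        const = float(pre.mean()) if pre.size else float(rec.f465.mean())
        if not bleach:
            proc["bleach_fit"] = {"constant_f0": const}
        if abs(const) <= 1e-12 * scale:
            proc["degenerate_zero_signal"] = True
            return DffTrace(t=t, dff=np.zeros_like(t), processing=proc)
        f0 = const

    dff = 100.0 * corrected / f0

    # 3. smoothing
    fs = rec.sampling_rate_hz
    win = max(int(round(options.smooth_window_s * fs)), 1)
    if win > 1:
        dff = uniform_filter1d(dff, size=win, mode="nearest")
    proc["smooth_samples"] = win
    return DffTrace(t=t, dff=dff, processing=proc)


# ---------------------------------------------------------------------------
# Transient detection
# ---------------------------------------------------------------------------

def _envelope_anchor_values(dff: np.ndarray, t: np.ndarray,
                            options: PhotometryOptions):
    """Return (anchor_times, anchor_values) describing the upper envelope."""
    if options.envelope == "interp":
        idx = argrelextrema(dff, np.greater)[0]
        anchors = np.concatenate(([0], idx, [len(dff) - 1]))
        anchors = np.unique(anchors)
        return t[anchors], dff[anchors]
    if options.envelope == "sliding":
        fs = 1.0 / (t[1] - t[0]) if len(t) > 1 else 1.0
        win = max(int(round(options.sliding_window_s * fs)), 1)
        env = maximum_filter1d(dff, size=win, mode="nearest")
        return t, env
    raise ValueError(f"unknown envelope method: {options.envelope!r}")


def _pair_valleys_peaks(times: np.ndarray, values: np.ndarray,
                        threshold: float):
    """Valley->next-peak pairing on the envelope sample sequence.

    Consecutive duplicates are collapsed, turning points (plus both
    boundaries) become the alternating valley/peak sequence, and each
    valley is paired with the immediately following peak; a pair whose rise
    strictly exceeds ``threshold`` yields one event stamped at the peak.
    """
    v = np.asarray(values, dtype=float)
    tt = np.asarray(times, dtype=float)
    if v.size < 2:
        return np.empty(0), np.empty(0)
    keep = np.concatenate(([True], v[1:] != v[:-1]))
    v, tt = v[keep], tt[keep]
    if v.size < 2:
        return np.empty(0), np.empty(0)
    s = np.sign(np.diff(v))                      # strictly +-1 after dedup
    change = np.nonzero(s[1:] != s[:-1])[0] + 1
    ext = np.concatenate(([0], change, [v.size - 1]))
    ev, ea = [], []
    # extrema alternate; the first is a valley iff the sequence starts rising
    start_is_valley = s[0] > 0
    for j in range(0 if start_is_valley else 1, ext.size - 1, 2):
        valley, peak = v[ext[j]], v[ext[j + 1]]
        if peak - valley > threshold:
            ev.append(tt[ext[j + 1]])
            ea.append(peak - valley)
    return np.asarray(ev), np.asarray(ea)


def detect_transients(dff: DffTrace, threshold_pct: float = 2.0,
                      options: PhotometryOptions = PhotometryOptions()
                      ) -> TransientSeries:
    """Detect transients on the envelope of a dF/F trace and build the
    1-minute binned, baseline-subtracted rate series.

    An event is a valley-to-peak rise of the envelope strictly exceeding
    ``threshold_pct`` (% dF/F); the event is stamped at the peak with the
    rise as its amplitude, and each peak is used at most once.
    """
    if threshold_pct <= 0:
        raise ValueError("threshold must be positive")
    if not np.all(np.isfinite(dff.dff)):
        raise ValueError("dF/F trace contains non-finite samples")
    if len(dff.dff) < 3 or np.ptp(dff.dff) == 0:
        return _binned_series(np.empty(0), np.empty(0), dff.t)

    at, av = _envelope_anchor_values(dff.dff, dff.t, options)
    ev_t, ev_a = _pair_valleys_peaks(at, av, threshold_pct)
    return _binned_series(ev_t, ev_a, dff.t)


def _session_bins(t: np.ndarray):
    """Half-open 1-minute bin left edges covering the session span."""
    lo = math.floor(t[0] / 60.0)
    hi = math.ceil(t[-1] / 60.0)
    if hi <= lo:
        hi = lo + 1
    return np.arange(lo, hi, dtype=float)


def _binned_series(ev_t: np.ndarray, ev_a: np.ndarray,
                   t: np.ndarray) -> TransientSeries:
    starts = _session_bins(t)
    edges = np.append(starts, starts[-1] + 1.0) * 60.0
    counts, _ = np.histogram(ev_t, bins=edges)
    rate = counts.astype(float)                  # events per 1-min bin
    base_mask = (starts >= BASELINE_WINDOW_MIN[0]) \
        & (starts < BASELINE_WINDOW_MIN[1])
    baseline = float(rate[base_mask].mean()) if base_mask.any() else 0.0
    return TransientSeries(event_times_s=ev_t, event_amplitudes_pct=ev_a,
                           bin_start_min=starts, binned_rate=rate,
                           baseline_rate=baseline,
                           delta_rate=rate - baseline)


def bin_dff(dff: DffTrace) -> tuple:
    """Mean dF/F per half-open 1-minute bin; returns (bin_start_min, values).

    Used for dopamine-sensor sessions, which are quantified on binned dF/F
    rather than discrete transients.
    """
    starts = _session_bins(dff.t)
    idx = np.floor(dff.t / 60.0).astype(int) - int(starts[0])
    sums = np.bincount(idx, weights=dff.dff, minlength=len(starts))
    ns = np.bincount(idx, minlength=len(starts))
    with np.errstate(invalid="ignore"):
        vals = sums / ns
    return starts, vals


# ---------------------------------------------------------------------------
# Session metrics
# ---------------------------------------------------------------------------

def _window_auc(starts: np.ndarray, values: np.ndarray, window) -> float:
    """Integral of the piecewise-constant binned series over ``window``
    (minutes); partial bin overlap contributes fractionally."""
    a, b = float(window[0]), float(window[1])
    if b <= a:
        raise ValueError("window must satisfy a < b")
    if a < starts[0] or b > starts[-1] + 1.0:
        raise ValueError(
            f"window [{a}, {b}] min lies outside the covered session span "
            f"[{starts[0]}, {starts[-1] + 1.0}] min")
    lo = np.maximum(starts, a)
    hi = np.minimum(starts + 1.0, b)
    overlap = np.clip(hi - lo, 0.0, None)
    return float(np.sum(values * overlap))


def session_metrics(series, options: PhotometryOptions = PhotometryOptions()
                    ) -> PhotometryMetrics:
    """Compute session metrics from a :class:`TransientSeries` or from a
    ``(bin_start_min, binned_dff)`` pair.

    For a transient series the integrand is the baseline-subtracted rate;
    for binned dF/F it is the baseline-subtracted dF/F, and ``peak_dff``
    (max post-injection binned dF/F) is also reported.

    ``time_to_baseline`` is the first 1-minute bin after the absolute peak
    of the baseline-subtracted series at which the series crosses back
    within ``baseline_return_tol`` of zero and stays there for
    ``baseline_return_bins`` consecutive bins; sessions that never return
    are censored at the session end.
    """
    peak_dff = None
    if isinstance(series, TransientSeries):
        starts, delta = series.bin_start_min, series.delta_rate
    else:
        starts, vals = series
        starts = np.asarray(starts, dtype=float)
        vals = np.asarray(vals, dtype=float)
        base_mask = (starts >= BASELINE_WINDOW_MIN[0]) \
            & (starts < BASELINE_WINDOW_MIN[1])
        baseline = float(vals[base_mask].mean()) if base_mask.any() else 0.0
        delta = vals - baseline
        post = starts >= 0.0
        if post.any():
            peak_dff = float(np.nanmax(vals[post]))

    auc_onset = _window_auc(starts, delta, options.onset_window_min)
    auc_offset = _window_auc(starts, delta, options.offset_window_min)

    post = np.nonzero(starts >= 0.0)[0]
    censored = True
    t_return = float(starts[-1] + 1.0)
    if post.size:
        peak_idx = post[np.argmax(np.abs(delta[post]))]
        sign = np.sign(delta[peak_idx]) or 1.0
        tol = options.baseline_return_tol
        ok = sign * delta <= tol
        need = options.baseline_return_bins
        for j in range(peak_idx + 1, len(starts) - need + 1):
            if ok[j: j + need].all():
                t_return = float(starts[j])
                censored = False
                break
    return PhotometryMetrics(auc_onset=auc_onset, auc_offset=auc_offset,
                             time_to_baseline=t_return, censored=censored,
                             peak_dff=peak_dff)
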
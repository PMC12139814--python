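"""AIM dyskinesia scoring and open-field velocity quantification.

Dyskinesia severity is rated on the Abnormal Involuntary Movement (AIM)
scale: axial, limb, and orolingual body segments are each scored 0-4 during
a one-minute observation window, for a maximum possible total of 12.  This
module computes segment totals, windowed area under the AIM timecourse,
time to AIM resolution, and 1-minute binned locomotor velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AimObservation",
    "AimTimecourse",
    "BehaviorMetrics",
    "total_aim",
    "aim_auc",
    "time_to_resolution",
    "bin_velocity",
    "speed_from_positions",
    "behavior_metrics",
]


@dataclass(frozen=True)
class AimObservation:
    """One scored observation: minutes post-injection plus per-segment
    scores, each an integer in {0..4}."""

    t_min: float
    axial: int
    limb: int
    orolingual: int

    def __post_init__(self):
        for name in ("axial", "limb", "orolingual"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= 4):
                raise ValueError(
                    f"{name} score must be an integer in 0..4, got {v!r}")

    @property
    def total(self) -> int:
        return int(self.axial + self.limb + self.orolingual)


@dataclass
class AimTimecourse:
    """Time-ordered AIM observations with a declared scoring schedule
    (``dense``: every minute for 20 min then every 5 min to 120;
    ``sparse``: every 20 min over 2 h)."""

    observations: list
    schedule: str = "dense"

    def __post_init__(self):
        t = self.t_min
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("observation times must be strictly increasing")

    @property
    def t_min(self) -> np.ndarray:
        return np.asarray([o.t_min for o in self.observations], dtype=float)

    @property
    def totals(self) -> np.ndarray:
        return np.asarray([o.total for o in self.observations], dtype=float)


@dataclass
class BehaviorMetrics:
    auc_onset: float
    auc_offset: float
    time_to_resolution: float
    censored: bool
    velocity_binned: np.ndarray | None = None


def total_aim(obs: AimObservation) -> int:
    """Total AIM score: the sum of the three body-segment scores (0-12)."""
    return obs.total


def aim_auc(tc: AimTimecourse, window, *, edge: str = "hold") -> float:
    """Trapezoidal area under the total-AIM timecourse over ``window``
    (minutes, [a, b]).

    Window edges falling between observations are filled by linear
    interpolation; edges outside the scored span use the ``edge`` policy:
    ``hold`` extends the nearest observation's value (default), ``zero``
    anchors with a score of 0.
    """
    a, b = float(window[0]), float(window[1])
    if a >= b:
        raise ValueError("window must satisfy a < b")
    t = tc.t_min
    y = tc.totals
    if t.size == 0:
        raise ValueError("empty timecourse")
    if edge == "hold":
        left_val, right_val = y[0], y[-1]
    elif edge == "zero":
        left_val, right_val = 0.0, 0.0
    else:
        raise ValueError(f"unknown edge policy {edge!r}")
    tt, yy = t, y
    if a < t[0]:
        tt = np.concatenate(([a], tt))
        yy = np.concatenate(([left_val], yy))
    if b > t[-1]:
        tt = np.concatenate((tt, [b]))
        yy = np.concatenate((yy, [right_val]))
    ya = np.interp(a, tt, yy)
    yb = np.interp(b, tt, yy)
    inside = (tt > a) & (tt < b)
    xs = np.concatenate(([a], tt[inside], [b]))
    ys = np.concatenate(([ya], yy[inside], [yb]))
    return float(np.trapezoid(ys, xs))


def time_to_resolution(tc: AimTimecourse) -> tuple:
    """Earliest scored time after the session's peak total AIM at which the
    total is 0 and remains 0 for every later observation.

    Returns ``(minutes, censored)``; censored sessions report the last
    scored timepoint.  A timecourse that never leaves 0 resolves trivially
    at its first timestamp.
    """
    t = tc.t_min
    y = tc.totals
    if t.size == 0:
        raise ValueError("empty timecourse")
    if not np.any(y > 0):
        return float(t[0]), False
    peak = int(np.argmax(y))
    # suffix all-zero test
    zero_from = np.concatenate((np.cumprod((y == 0)[::-1])[::-1], [1]))
    for j in range(peak + 1, t.size):
        if y[j] == 0 and zero_from[j]:
            return float(t[j]), False
    return float(t[-1]), True


def speed_from_positions(x_cm: np.ndarray, y_cm: np.ndarray,
                         fs_hz: float) -> np.ndarray:
    """Instantaneous speed (cm/s) from tracked center-of-gravity positions;
    forward differences, length ``n - 1``."""
    dx = np.diff(np.asarray(x_cm, dtype=float))
    dy = np.diff(np.asarray(y_cm, dtype=float))
    return np.hypot(dx, dy) * fs_hz


def bin_velocity(speed_cm_s: np.ndarray, fs_hz: float) -> np.ndarray:
    """Mean speed per half-open 1-minute bin; the partial trailing bin is
    dropped."""
    speed = np.asarray(speed_cm_s, dtype=float)
    bad = ~np.isfinite(speed)
    if bad.any():
        raise ValueError(
            "non-finite speed samples at indices "
            f"{np.nonzero(bad)[0][:10].tolist()}")
    per_bin = int(round(60.0 * fs_hz))
    n_bins = speed.size // per_bin
    if n_bins == 0:
        return np.empty(0)
    return speed[: n_bins * per_bin].reshape(n_bins, per_bin).mean(axis=1)


def behavior_metrics(tc: AimTimecourse,
                     onset_window=(0.0, 20.0), offset_window=(30.0, 90.0),
                     velocity_binned: np.ndarray | None = None
                     ) -> BehaviorMetrics:
    """AIM AUC over the dyskinesia onset and offset windows plus time to
    resolution, bundled for the session table."""
    ttr, cens = time_to_resolution(tc)
    return BehaviorMetrics(
        auc_onset=aim_auc(tc, onset_window),
        auc_offset=aim_auc(tc, offset_window),
        time_to_resolution=ttr, censored=cens,
        velocity_binned=velocity_binned)
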
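"""Session-bundle container and tabular I/O.

A session bundle is an HDF5 file with the layout::

    /photometry/{t, f465, f405}      attrs: indicator, cell_class,
                                     treatment_timepoint, subject
    /aim/{t_min, axial, limb, orolingual}    attrs: schedule
    /velocity/speed_cm_s             attrs: fs_hz
    /units/<id>/spike_times          attrs: peak_to_valley_ms, peak_width_ms
    /sweeps/<id>/{t, command, recorded}      attrs: mode (on /sweeps)

All times are stored in seconds relative to the injection (the reporting
layer converts to minutes).  Tabular outputs are CSV (UTF-8, '.' decimal);
configurations and manifests are YAML.  Validation problems found while
reading are aggregated into a single error that names every offending
field.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
import yaml

from .behavior import AimObservation, AimTimecourse
from .photometry import PhotometryRecording
from .slice_ephys import Sweep, SweepSet
from .units import UnitRecording

__all__ = [
    "SessionBundle",
    "BundleValidationError",
    "write_bundle",
    "read_bundle",
    "write_ground_truth_csv",
    "load_manifest",
    "save_config",
    "load_config",
]

SCHEMA_VERSION = 1
TIMEPOINTS = ("saline", "day1", "day3", "day4", "day5",
              "week2", "week3", "week4")


class BundleValidationError(ValueError):
    """All schema problems found in a bundle, reported together."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("bundle validation failed:\n  - "
                         + "\n  - ".join(self.problems))


@dataclass
class SessionBundle:
    """Typed contents of one session bundle; absent modalities are None."""

    photometry: PhotometryRecording | None = None
    units: list | None = None
    aim: AimTimecourse | None = None
    velocity_cm_s: np.ndarray | None = None
    velocity_fs_hz: float | None = None
    sweeps: SweepSet | None = None
    meta: dict = field(default_factory=dict)


def write_bundle(path, bundle: SessionBundle) -> None:
    """Write a session bundle to ``path`` (HDF5)."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        for k, v in bundle.meta.items():
            f.attrs[k] = v
        if bundle.photometry is not None:
            g = f.create_group("photometry")
            rec = bundle.photometry
            g.create_dataset("t", data=rec.t)
            g.create_dataset("f465", data=rec.f465)
            g.create_dataset("f405", data=rec.f405)
            for k, v in rec.meta.items():
                g.attrs[k] = v
        if bundle.aim is not None:
            g = f.create_group("aim")
            g.attrs["schedule"] = bundle.aim.schedule
            g.create_dataset("t_min", data=bundle.aim.t_min)
            for name in ("axial", "limb", "orolingual"):
                g.create_dataset(name, data=np.asarray(
                    [getattr(o, name) for o in bundle.aim.observations],
                    dtype=np.int8))
        if bundle.velocity_cm_s is not None:
            g = f.create_group("velocity")
            g.create_dataset("speed_cm_s", data=bundle.velocity_cm_s)
            g.attrs["fs_hz"] = bundle.velocity_fs_hz or 1.0
        if bundle.units is not None:
            g = f.create_group("units")
            for u in bundle.units:
                gu = g.create_group(u.unit_id)
                gu.create_dataset("spike_times", data=u.spike_times)
                gu.attrs["peak_to_valley_ms"] = u.peak_to_valley_ms
                gu.attrs["peak_width_ms"] = u.peak_width_ms
                gu.attrs["subject"] = u.subject
                gu.attrs["treatment_timepoint"] = u.treatment_timepoint
                if u.session_span_s is not None:
                    gu.attrs["session_span_s"] = list(u.session_span_s)
        if bundle.sweeps is not None:
            g = f.create_group("sweeps")
            g.attrs["mode"] = bundle.sweeps.mode
            g.attrs["sampling_rate_hz"] = bundle.sweeps.sampling_rate_hz
            for i, sw in enumerate(bundle.sweeps.sweeps):
                gs = g.create_group(f"sweep{i:03d}")
                gs.create_dataset("t", data=sw.t)
                gs.create_dataset("command", data=sw.command)
                gs.create_dataset("recorded", data=sw.recorded)


def read_bundle(path) -> SessionBundle:
    """Read and validate a session bundle.

    Missing optional groups simply leave the corresponding field ``None``;
    structural problems (length mismatches, missing required datasets,
    unsupported schema) are aggregated into one
    :class:`BundleValidationError`.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    problems = []
    out = SessionBundle()
    with h5py.File(path, "r") as f:
        ver = int(f.attrs.get("schema_version", -1))
        if ver != SCHEMA_VERSION:
            problems.append(f"unsupported schema_version {ver}")
        out.meta = {k: _from_h5(v) for k, v in f.attrs.items()}
        if "photometry" in f:
            g = f["photometry"]
            missing = [k for k in ("t", "f465", "f405") if k not in g]
            if missing:
                problems.append(f"/photometry missing datasets {missing}")
            else:
                t = g["t"][:]
                f465, f405 = g["f465"][:], g["f405"][:]
                if not (len(t) == len(f465) == len(f405)):
                    problems.append(
                        "/photometry length mismatch: "
                        f"t={len(t)} f465={len(f465)} f405={len(f405)}")
                else:
                    try:
                        out.photometry = PhotometryRecording(
                            t=t, f465=f465, f405=f405,
                            meta={k: _from_h5(v) for k, v in g.attrs.items()})
                    except ValueError as e:
                        problems.append(f"/photometry: {e}")
        if "aim" in f:
            g = f["aim"]
            try:
                obs = [AimObservation(t_min=float(tm), axial=int(a),
                                      limb=int(l), orolingual=int(o))
                       for tm, a, l, o in zip(g["t_min"][:], g["axial"][:],
                                              g["limb"][:],
                                              g["orolingual"][:])]
                out.aim = AimTimecourse(
                    observations=obs,
                    schedule=str(_from_h5(g.attrs.get("schedule", "dense"))))
            except (KeyError, ValueError) as e:
                problems.append(f"/aim: {e}")
        if "velocity" in f:
            g = f["velocity"]
            if "speed_cm_s" not in g:
                problems.append("/velocity missing speed_cm_s")
            else:
                out.velocity_cm_s = g["speed_cm_s"][:]
                out.velocity_fs_hz = float(g.attrs.get("fs_hz", 1.0))
        if "units" in f:
            units = []
            for uid in sorted(f["units"]):
                gu = f["units"][uid]
                try:
                    span = gu.attrs.get("session_span_s")
                    units.append(UnitRecording(
                        spike_times=gu["spike_times"][:],
                        peak_to_valley_ms=float(
                            gu.attrs.get("peak_to_valley_ms", 0.5)),
                        peak_width_ms=float(
                            gu.attrs.get("peak_width_ms", 0.2)),
                        unit_id=uid,
                        subject=str(_from_h5(gu.attrs.get("subject", ""))),
                        treatment_timepoint=str(
                            _from_h5(gu.attrs.get("treatment_timepoint", ""))),
                        session_span_s=tuple(span) if span is not None
                        else None))
                except (KeyError, ValueError) as e:
                    problems.append(f"/units/{uid}: {e}")
            out.units = units
        if "sweeps" in f:
            g = f["sweeps"]
            sweeps = []
            for sid in sorted(g):
                gs = g[sid]
                try:
                    sweeps.append(Sweep(t=gs["t"][:], command=gs["command"][:],
                                        recorded=gs["recorded"][:]))
                except (KeyError, ValueError) as e:
                    problems.append(f"/sweeps/{sid}: {e}")
            try:
                out.sweeps = SweepSet(
                    sweeps=sweeps, mode=str(_from_h5(g.attrs["mode"])),
                    sampling_rate_hz=float(g.attrs["sampling_rate_hz"]))
            except KeyError as e:
                problems.append(f"/sweeps missing attribute {e}")
    if problems:
        raise BundleValidationError(problems)
    return out


def _from_h5(v):
    if isinstance(v, bytes):
        return v.decode()
    if isinstance(v, np.generic):
        return v.item()
    return v


def write_ground_truth_csv(outdir, truth, prefix: str = "") -> None:
    """Ground-truth sidecars: transients.csv and labels.csv when the
    corresponding fields are populated."""
    os.makedirs(outdir, exist_ok=True)
    if truth.transient_times_s is not None:
        pd.DataFrame({
            "t_s": truth.transient_times_s,
            "amplitude_pct": truth.transient_amplitudes_pct,
        }).to_csv(os.path.join(outdir, prefix + "transients.csv"),
                  index=False)
    if truth.unit_labels is not None:
        pd.DataFrame({
            "unit_index": np.arange(len(truth.unit_labels)),
            "label": truth.unit_labels,
            "cell_type": truth.unit_cell_types,
        }).to_csv(os.path.join(outdir, prefix + "labels.csv"), index=False)


def load_manifest(path) -> list:
    """Load a YAML manifest: a list of session entries with subject,
    treatment timepoint, bundle path, and optional seed.  Referenced bundle
    files must exist."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    sessions = doc.get("sessions", doc if isinstance(doc, list) else [])
    base = os.path.dirname(os.path.abspath(path))
    problems = []
    for s in sessions:
        if "path" not in s:
            problems.append(f"session entry without path: {s}")
            continue
        if not os.path.isabs(s["path"]):
            s["path"] = os.path.join(base, s["path"])
        if not os.path.exists(s["path"]):
            problems.append(f"missing bundle file {s['path']}")
        tp = s.get("timepoint")
        if tp is not None and tp not in TIMEPOINTS:
            problems.append(f"unknown timepoint {tp!r} (expected one of "
                            f"{TIMEPOINTS})")
    if problems:
        raise BundleValidationError(problems)
    return sessions


def save_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
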
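"""End-to-end session pipeline: bundle -> per-session metrics -> session table.

Each session bundle is processed with whatever modalities it contains:
photometry preprocessing + transient detection + session metrics, AIM and
velocity metrics, unit screening + response classification, and slice sweep
summaries.  Failures are recorded per session and the remaining sessions
continue; the run is deterministic given identical inputs and
configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os

import numpy as np
import pandas as pd

from . import behavior, photometry, slice_ephys, units as units_mod
from .io import SessionBundle, load_manifest, read_bundle

logger = logging.getLogger(__name__)

__all__ = ["analyze_session", "run_pipeline"]


def analyze_session(bundle: SessionBundle,
                    options: photometry.PhotometryOptions =
                    photometry.PhotometryOptions()) -> dict:
    """Quantify one session bundle; returns a flat dict of session metrics
    plus nested per-unit/per-sweep outputs."""
    row: dict = {"subject": bundle.meta.get("subject", ""),
                 "timepoint": bundle.meta.get("timepoint", "")}
    extras: dict = {}

    if bundle.photometry is not None:
        rec = bundle.photometry
        dff = photometry.preprocess_dff(rec, options)
        indicator = str(rec.meta.get("indicator", "")).upper()
        if indicator.startswith("GRAB"):
            # dopamine sensor: quantified on binned dF/F, no event detection
            m = photometry.session_metrics(photometry.bin_dff(dff), options)
            row.update(peak_dff_pct=m.peak_dff,
                       dff_auc_onset=m.auc_onset,
                       dff_auc_offset=m.auc_offset)
        else:
            series = photometry.detect_transients(
                dff, options.threshold_pct, options)
            m = photometry.session_metrics(series, options)
            row.update(
                transient_baseline_rate_per_min=series.baseline_rate,
                transient_auc_onset=m.auc_onset,
                transient_auc_offset=m.auc_offset,
                time_to_baseline_min=m.time_to_baseline,
                time_to_baseline_censored=m.censored,
                n_transients=len(series.event_times_s))
            extras["transients"] = series
        extras["dff_processing"] = dff.processing

    if bundle.aim is not None:
        vel = None
        if bundle.velocity_cm_s is not None:
            vel = behavior.bin_velocity(bundle.velocity_cm_s,
                                        bundle.velocity_fs_hz or 1.0)
        bm = behavior.behavior_metrics(bundle.aim, velocity_binned=vel)
        row.update(aim_auc_onset=bm.auc_onset, aim_auc_offset=bm.auc_offset,
                   time_to_resolution_min=bm.time_to_resolution,
                   time_to_resolution_censored=bm.censored)
        if vel is not None:
            row["mean_velocity_cm_s"] = float(np.mean(vel)) if len(vel) else np.nan

    if bundle.units:
        cls = []
        for u in bundle.units:
            su_pass, cell_type, _ = units_mod.screen_unit(u)
            if not (su_pass and cell_type == "putative_MSN"):
                continue   # only clean putative MSNs are classified
            cls.append(units_mod.classify_response(u))
        extras["unit_classifications"] = cls
        counts = {"increase": 0, "decrease": 0, "none": 0}
        for c in cls:
            counts[c.response] += 1
        row.update(n_units=len(cls),
                   n_putative_d1=counts["increase"],
                   n_putative_d2=counts["decrease"],
                   n_no_change=counts["none"])
        deltas = [c.delta_rate_hz for c in cls if c.response != "none"]
        row["mean_delta_rate_hz"] = float(np.mean(deltas)) if deltas else np.nan

    if bundle.sweeps is not None:
        if bundle.sweeps.mode == "current_clamp":
            prof = slice_ephys.excitability(bundle.sweeps)
            row.update(rheobase_pa=prof.rheobase_pa,
                       ap_threshold_mv=prof.ap_threshold_mv,
                       ap_half_width_ms=prof.half_width_ms,
                       ahp_mv=prof.ahp_mv, rmp_mv=prof.rmp_mv)
            extras["excitability"] = prof
        else:
            mini = slice_ephys.detect_minis(bundle.sweeps)
            row.update(mepsc_frequency_hz=mini.frequency_hz,
                       mepsc_amplitude_pa=mini.mean_amplitude_pa,
                       mepsc_included=mini.included,
                       n_mepsc=len(mini.event_times_s))
            extras["minis"] = mini
    row["_extras"] = extras
    return row


def run_pipeline(manifest_path, out_dir,
                 options: photometry.PhotometryOptions =
                 photometry.PhotometryOptions()) -> tuple:
    """Run every session in a manifest; write per-session CSVs and the
    session table.

    Returns ``(session_table, n_failed)``.  A failing session is logged and
    recorded with an ``error`` column; remaining sessions still run.
    """
    sessions = load_manifest(manifest_path)
    os.makedirs(out_dir, exist_ok=True)
    logger.info("pipeline options: %s", dataclasses.asdict(options))
    rows = []
    n_failed = 0
    for s in sessions:
        label = f"{s.get('subject', '?')}/{s.get('timepoint', '?')}"
        try:
            bundle = read_bundle(s["path"])
            bundle.meta.setdefault("subject", s.get("subject", ""))
            bundle.meta["subject"] = s.get("subject", bundle.meta["subject"])
            if s.get("timepoint"):
                bundle.meta["timepoint"] = s["timepoint"]
            row = analyze_session(bundle, options)
            extras = row.pop("_extras")
            _write_session_outputs(out_dir, label.replace("/", "_"), extras)
            rows.append(row)
        except Exception as e:          # keep going; report at the end
            logger.error("session %s failed: %s", label, e)
            rows.append({"subject": s.get("subject", ""),
                         "timepoint": s.get("timepoint", ""),
                         "error": str(e)})
            n_failed += 1
    table = pd.DataFrame(rows)
    table.to_csv(os.path.join(out_dir, "session_table.csv"), index=False)
    return table, n_failed


def _write_session_outputs(out_dir, stem, extras) -> None:
    if "transients" in extras:
        s = extras["transients"]
        pd.DataFrame({
            "bin_start_min": s.bin_start_min,
            "rate_per_min": s.binned_rate,
            "delta_rate_per_min": s.delta_rate,
        }).to_csv(os.path.join(out_dir, f"{stem}_transient_bins.csv"),
                  index=False)
    if "unit_classifications" in extras:
        pd.DataFrame([dataclasses.asdict(c)
                      for c in extras["unit_classifications"]]).to_csv(
            os.path.join(out_dir, f"{stem}_units.csv"), index=False)
    if "minis" in extras:
        m = extras["minis"]
        rows = [{"cell_id": stem, "quantity": "iei", "value": v}
                for v in m.cumulative_iei_s]
        rows += [{"cell_id": stem, "quantity": "amplitude", "value": v}
                 for v in m.cumulative_amplitude_pa]
        pd.DataFrame(rows).to_csv(
            os.path.join(out_dir, f"{stem}_mepsc_cumulative.csv"),
            index=False)
    if "dff_processing" in extras:
        with open(os.path.join(out_dir, f"{stem}_processing.json"),
                  "w") as fh:
            json.dump(extras["dff_processing"], fh, indent=1, default=str)
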
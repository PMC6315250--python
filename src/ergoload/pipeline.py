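"""End-to-end orchestration: synchronize, calibrate, detect, summarize, analyze.

``run_day_pipeline`` chains the per-day stages on a directory of signal
files (or in-memory recordings): trigger/rotation landmark detection and
sync fitting, EMG preprocessing and threshold calibration, N-pose and
inclination processing, epoch feature extraction and event labeling per
threshold mode, plus step and heart-rate summaries.  ``run_trial_pipeline``
fits the unadjusted and adjusted mixed models on a trial table.  Both are
deterministic given inputs and seed, and every summary carries the seed and
a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ergoload import emg as emg_mod
from ergoload import events as ev_mod
from ergoload import kinematics as kin_mod
from ergoload import sync as sync_mod
from ergoload.errors import ErgoloadError
from ergoload.io import (
    SignalRecording,
    read_annotations,
    read_recording,
    segments_of,
    write_annotations,
    write_recording,
)
from ergoload.simulate import SyntheticDay

logger = logging.getLogger(__name__)

MUSCLES = ("TrpR", "TrpL", "ESR", "ESL")


@dataclass
class PipelineConfig:
    """Processing parameters shared by all stages."""

    modes: tuple[str, ...] = ("ref100", "ref150", "mvc50")
    two_muscle_rule_only: bool = False
    rms_window_s: float = 0.5
    rms_overlap_frac: float = 0.2
    epoch_s: float = 10.0
    muscles: tuple[str, ...] = MUSCLES
    seed: int = 0

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class DayResult:
    """Outputs of the per-day pipeline."""

    summary: dict
    thresholds: emg_mod.MuscleThresholds
    features: list[ev_mod.EpochFeatures]
    event_series: dict[str, ev_mod.EventSeries]
    sync_back: sync_mod.SyncModel
    sync_thigh: sync_mod.SyncModel


def _stage(name: str):
    """Decorator tagging stage errors with the stage name."""

    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ErgoloadError as e:
                raise type(e)(f"[stage {name}] {e}") from e

        return wrapper

    return deco


def write_day(day: SyntheticDay, outdir: str | Path, fmt: str = "%.17g") -> None:
    """Write a synthetic day in the pipeline's on-disk layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, rec in (
        ("emg", day.emg),
        ("imu_back", day.imu_back),
        ("imu_thigh", day.imu_thigh),
        ("heart", day.heart),
    ):
        write_recording(rec, outdir / f"{name}.tsv", fmt=fmt)
    write_annotations(day.annotations, outdir / "annotations.json")
    day.ground_truth.to_csv(outdir / "ground_truth.csv", index=False)


def load_day(signals_dir: str | Path):
    """Read the four streams and annotations written by :func:`write_day`."""
    d = Path(signals_dir)
    recs = {
        name: read_recording(d / f"{name}.tsv")
        for name in ("emg", "imu_back", "imu_thigh", "heart")
    }
    return recs, read_annotations(d / "annotations.json")


def run_day_pipeline(
    recordings: dict[str, SignalRecording],
    annotations,
    cfg: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> DayResult:
    """Run synchronize -> calibrate -> detect -> summarize on one day.

    ``recordings`` maps ``emg``, ``imu_back``, ``imu_thigh``, ``heart`` to
    recordings; annotation times are on the EMG clock.  When ``outdir`` is
    given, thresholds, per-mode event logs and a JSON day summary are
    written there.
    """
    cfg = cfg or PipelineConfig()
    emg_rec = recordings["emg"]

    # --- synchronization ---------------------------------------------------
    pulses = _stage("sync")(sync_mod.detect_emg_trigger)(emg_rec)
    syncs = {}
    for site in ("imu_back", "imu_thigh"):
        rotations = _stage("sync")(sync_mod.detect_imu_rotation)(recordings[site])
        syncs[site] = _stage("sync")(sync_mod.fit_sync)(pulses, rotations)
        logger.info(
            "sync %s: offset %.3f s, drift %.1f ppm, residual %.4f s",
            site, syncs[site].offset_s, syncs[site].drift_ppm, syncs[site].residual_s,
        )

    # --- EMG calibration and thresholds -------------------------------------
    filtered = _stage("calibrate")(emg_mod.preprocess_emg)(emg_rec, channels=list(cfg.muscles))
    cal = _stage("calibrate")(emg_mod.calibration_from_recording)(
        filtered, annotations, list(cfg.muscles)
    )
    thresholds = _stage("calibrate")(emg_mod.build_thresholds)(cal)

    # --- kinematics ----------------------------------------------------------
    npose_seg = segments_of(annotations, "npose")[0]
    work_seg = segments_of(annotations, "work")[0]
    back = recordings["imu_back"]
    sm = syncs["imu_back"]
    npose_stream = (
        float(sm.to_stream_time(npose_seg.start_s)),
        float(sm.to_stream_time(npose_seg.end_s)),
    )
    from ergoload.io import SegmentAnnotation

    ncal = _stage("kinematics")(kin_mod.calibrate_npose)(
        back, SegmentAnnotation("npose", *npose_stream)
    )
    work_stream = (
        float(sm.to_stream_time(work_seg.start_s)),
        float(sm.to_stream_time(work_seg.end_s)),
    )
    incl = _stage("kinematics")(kin_mod.inclination_series)(
        back.slice_seconds(*work_stream), ncal
    )
    incl.times = np.asarray(sm.to_emg_time(incl.times))  # express on the EMG clock

    # --- event detection -----------------------------------------------------
    work_emg = filtered.slice_seconds(work_seg.start_s, work_seg.end_s)
    rms = {
        m: emg_mod.rms_windows(
            work_emg.channel(m), work_emg.fs, cfg.rms_window_s, cfg.rms_overlap_frac,
            t0=work_emg.t0,
        )
        for m in cfg.muscles
    }
    feats = _stage("detect")(ev_mod.epoch_features)(
        rms, incl, (work_seg.start_s, work_seg.end_s), cfg.epoch_s
    )
    series: dict[str, ev_mod.EventSeries] = {}
    counts: dict[str, dict] = {}
    for mode in cfg.modes:
        es = _stage("detect")(ev_mod.label_events)(
            feats, thresholds, mode, two_muscle_rule_only=cfg.two_muscle_rule_only
        )
        series[mode] = es
        n, rate = ev_mod.count_events(es, cfg.epoch_s)
        counts[mode] = {"count": n, "per_hour": rate}
        logger.info("mode %s: %d events (%.2f/h)", mode, n, rate)

    # --- activity summaries --------------------------------------------------
    thigh_sm = syncs["imu_thigh"]
    thigh_work = (
        float(thigh_sm.to_stream_time(work_seg.start_s)),
        float(thigh_sm.to_stream_time(work_seg.end_s)),
    )
    steps, steps_per_h = _stage("summarize")(kin_mod.count_steps)(
        recordings["imu_thigh"], thigh_work
    )
    hr = _stage("summarize")(kin_mod.summarize_heart_rate)(
        recordings["heart"], (work_seg.start_s, work_seg.end_s)
    )

    n_valid = series[cfg.modes[0]].n_valid if cfg.modes else len(feats)
    summary = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "work_interval_s": [work_seg.start_s, work_seg.end_s],
        "work_duration_h": (work_seg.end_s - work_seg.start_s) / 3600.0,
        "n_epochs": len(feats),
        "n_valid_epochs": n_valid,
        "events": counts,
        "steps": steps,
        "steps_per_hour": steps_per_h,
        "heart_rate": hr,
        "sync": {
            site: {"offset_s": m.offset_s, "drift_ppm": m.drift_ppm, "residual_s": m.residual_s}
            for site, m in syncs.items()
        },
        "thresholds_mv": thresholds.base,
        "single_session_muscles": [m for m, f in thresholds.single_session.items() if f],
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "thresholds.json").write_text(json.dumps(thresholds.to_dict(), indent=1))
        for mode, es in series.items():
            ev_mod.export_event_log(es, feats, outdir / f"events_{mode}.csv", thresholds)
        (outdir / "day_summary.json").write_text(json.dumps(summary, indent=1))

    return DayResult(
        summary=summary,
        thresholds=thresholds,
        features=feats,
        event_series=series,
        sync_back=syncs["imu_back"],
        sync_thigh=syncs["imu_thigh"],
    )


def run_trial_pipeline(
    trial: pd.DataFrame | str | Path,
    cfg: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Fit the unadjusted and adjusted trial models and emit a result bundle."""
    from ergoload import stats as stats_mod

    cfg = cfg or PipelineConfig()
    if not isinstance(trial, pd.DataFrame):
        trial = pd.read_csv(trial)
    unadj = stats_mod.fit_itt_model(trial, adjusted=False)
    adj = stats_mod.fit_itt_model(trial, adjusted=True)
    baseline = stats_mod.baseline_tests(trial)
    out = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "unadjusted": unadj.to_dict(),
        "adjusted": adj.to_dict(),
        "baseline_tests": baseline.to_dict(orient="records"),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "trial_results.json").write_text(json.dumps(out, indent=1, default=float))
        baseline.to_csv(outdir / "baseline_tests.csv", index=False)
    return out
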
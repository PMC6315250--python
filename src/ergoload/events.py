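"""Epoch-based detection of excessive physical workload events.

Working time is tiled into nonoverlapping 10-second epochs.  For each epoch
the 90th percentile of the 500 ms RMS windows starting inside it summarizes
each muscle's amplitude, and the 90th percentile of the within-epoch
inclination samples summarizes posture.  An epoch is labeled an *event*
when either

* at least two of the four muscles exceed their base threshold, or
* one erector spinae side exceeds its *inclination-modified* threshold —
  the base threshold linearly decayed to half at 90 degrees forward or 30
  degrees sideways trunk inclination (fixed beyond those angles, taking the
  lower of the two decayed values).

The modified threshold reflects that low-back load at a given sEMG
amplitude is higher when the trunk is flexed.  Threshold crossing is strict
(ties are non-events), and invalid epochs (too few RMS windows or mostly
invalid inclination) are never events.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ergoload.emg import MuscleThresholds, RmsSeries
from ergoload.errors import ConfigurationError
from ergoload.kinematics import InclinationSeries

EPOCH_S = 10.0
MIN_RMS_WINDOWS = 5
MAX_INVALID_INCL_FRAC = 0.5
FWD_HALF_DEG = 90.0
SIDE_HALF_DEG = 30.0

ES_MUSCLES = ("ESR", "ESL")


@dataclass
class EpochFeatures:
    """Summary features of one 10-s work epoch."""

    epoch_index: int
    start_s: float
    p90_rms_mv: dict[str, float]
    fwd_deg: float
    side_deg: float
    valid: bool = True


@dataclass
class EventSeries:
    """Per-epoch event labels for one threshold mode."""

    mode: str
    labels: np.ndarray
    rule_trace: list[str]
    n_valid: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)

    @property
    def count(self) -> int:
        return int(np.sum(self.labels))


def epoch_features(
    rms: dict[str, RmsSeries],
    incl: InclinationSeries | None,
    work: tuple[float, float],
    epoch_s: float = EPOCH_S,
) -> list[EpochFeatures]:
    """Per-epoch 90th-percentile features over the work interval.

    Epochs are aligned to the start of the annotated work interval; a
    trailing partial epoch is dropped.  A muscle contributes the RMS windows
    whose *start* lies in the epoch; an epoch is invalid when any muscle has
    fewer than 5 windows or more than half of its inclination samples are
    flagged.  Without an inclination stream the posture summaries are 0 and
    only the two-muscle rule can fire downstream.
    """
    start, end = work
    if end <= start:
        return []
    n_epochs = int(np.floor((end - start) / epoch_s))
    feats: list[EpochFeatures] = []
    for k in range(n_epochs):
        e0 = start + k * epoch_s
        e1 = e0 + epoch_s
        p90: dict[str, float] = {}
        valid = True
        for muscle, series in rms.items():
            sel = (series.times >= e0 - 1e-9) & (series.times < e1 - 1e-9)
            vals = series.values[sel]
            if len(vals) < MIN_RMS_WINDOWS:
                valid = False
                p90[muscle] = float(np.percentile(vals, 90)) if len(vals) else 0.0
            else:
                p90[muscle] = float(np.percentile(vals, 90))
        fwd = side = 0.0
        if incl is not None:
            sel = (incl.times >= e0 - 1e-9) & (incl.times < e1 - 1e-9)
            v = incl.valid[sel]
            if len(v) == 0 or np.mean(~v) > MAX_INVALID_INCL_FRAC:
                valid = False
            if v.any():
                # upper order statistic: a full second of deep flexion within
                # the epoch registers at its full angle
                fwd = float(np.percentile(incl.forward_deg[sel][v], 90, method="higher"))
                side = float(np.percentile(incl.sideways_deg[sel][v], 90, method="higher"))
        feats.append(
            EpochFeatures(
                epoch_index=k, start_s=e0, p90_rms_mv=p90, fwd_deg=fwd, side_deg=side, valid=valid
            )
        )
    return feats


def modified_threshold(base: float, fwd_deg: float, side_deg: float) -> float:
    """Inclination-decayed erector spinae threshold (mV).

    Linear decay to ``base/2`` at 90 degrees forward or 30 degrees sideways,
    constant beyond; the lower of the forward- and sideways-decayed values
    is returned.  The result always lies in ``[base/2, base]``.
    """
    if base <= 0:
        raise ValueError(f"base threshold must be positive, got {base}")
    t_f = base * (1.0 - 0.5 * min(abs(fwd_deg), FWD_HALF_DEG) / FWD_HALF_DEG)
    t_s = base * (1.0 - 0.5 * min(abs(side_deg), SIDE_HALF_DEG) / SIDE_HALF_DEG)
    return min(t_f, t_s)


def label_events(
    feats: list[EpochFeatures],
    th: MuscleThresholds,
    mode: str = "ref100",
    two_muscle_rule_only: bool = False,
    es_muscles: tuple[str, str] = ES_MUSCLES,
) -> EventSeries:
    """Label each epoch as event / non-event under one threshold mode.

    The two-muscle rule compares every muscle's epoch P90 against its base
    (unmodified) threshold; the modified-threshold rule applies to the two
    erector spinae channels only.  ``two_muscle_rule_only=True`` disables
    the latter (exploratory variant).  Invalid epochs are never events.
    """
    for muscle in th.muscles:
        th.threshold(mode, muscle)  # raises ConfigurationError if absent
    labels = np.zeros(len(feats), dtype=bool)
    trace: list[str] = [""] * len(feats)
    n_valid = 0
    for i, f in enumerate(feats):
        if not f.valid:
            continue
        n_valid += 1
        n_over = sum(
            1 for m in th.muscles if f.p90_rms_mv.get(m, 0.0) > th.threshold(mode, m)
        )
        fired: list[str] = []
        if n_over >= 2:
            fired.append("two_muscle")
        if not two_muscle_rule_only:
            for m in es_muscles:
                if m not in th.muscles:
                    raise ConfigurationError(f"erector spinae muscle {m!r} has no threshold")
                mod = modified_threshold(th.threshold(mode, m), f.fwd_deg, f.side_deg)
                if f.p90_rms_mv.get(m, 0.0) > mod:
                    fired.append("modified_es")
                    break
        if fired:
            labels[i] = True
            trace[i] = "+".join(fired)
    return EventSeries(mode=mode, labels=labels, rule_trace=trace, n_valid=n_valid)


def count_events(series: EventSeries, epoch_s: float = EPOCH_S) -> tuple[int, float]:
    """Event count and events/hour normalized by valid work duration."""
    valid_hours = series.n_valid * epoch_s / 3600.0
    rate = series.count / valid_hours if valid_hours > 0 else 0.0
    return series.count, rate


def export_event_log(
    series: EventSeries,
    feats: list[EpochFeatures],
    path: str | Path,
    th: MuscleThresholds | None = None,
) -> None:
    """CSV log of event epochs for manual video lookup.

    One row per event epoch: start time, muscles over their base threshold,
    posture summaries, mode and the rule that fired.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["start_s", "mode", "rule", "muscles_over", "fwd_deg", "side_deg"])
        for f, lab, rule in zip(feats, series.labels, series.rule_trace):
            if not lab:
                continue
            over = ""
            if th is not None:
                over = "+".join(
                    m for m in th.muscles if f.p90_rms_mv.get(m, 0.0) > th.threshold(series.mode, m)
                )
            w.writerow([f.start_s, series.mode, rule, over, round(f.fwd_deg, 2), round(f.side_deg, 2)])
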
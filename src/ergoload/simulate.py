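"""Synthetic measurement days and trial outcome tables with known ground truth.

The day generator emulates a field measurement day: a pre-day sync landmark
(2 mV trigger pulse on the EMG logger + fast 95 degree IMU rotation), the
calibration protocol (3 maximal voluntary contractions per muscle group
with rests, 10 reference-lift cycles, a 15 s N-pose), several hours of
work with embedded high-load episodes at known epochs, and a post-day sync
landmark.  Surface EMG is modeled as amplitude-modulated Gaussian noise
band-limited to 20-450 Hz — the downstream algorithm consumes only RMS
amplitude, so spectral realism beyond bandwidth is unnecessary.  The upper
back IMU renders the gravity vector for the scripted trunk inclination
trace, the thigh IMU carries a 2 Hz gait impact train during walking
intervals, and heart rate is baseline plus load-linked increments.

The trial generator draws log event counts from the linear mixed model of a
two-arm cluster-randomized design (random cluster and subject intercepts,
fixed arm, time and arm-by-time effects) with missing-at-random follow-ups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from ergoload.errors import ScenarioError
from ergoload.io import SegmentAnnotation, SignalRecording

MUSCLES = ("TrpR", "TrpL", "ESR", "ESL")
EMG_FS = 1024.0
IMU_FS = 100.0
HR_FS = 1.0
EPOCH_S = 10.0

# protocol timing (s)
PRE_IDLE = 10.0
SYNC_PULSE_S = 0.2
MVC_RAMP_S = 2.5
MVC_HOLD_S = 3.0
MVC_REST_S = 30.0
LIFT_CYCLE_S = 6.0
LIFT_ACTIVE_S = 4.0
N_LIFTS = 10
NPOSE_S = 15.0
ROTATION_DEG = 95.0
ROTATION_S = 0.2


@dataclass
class DayEvent:
    """One scripted overload episode, aligned to the 10-s epoch grid.

    ``start_s`` is relative to the start of the work interval; ``intensity``
    multiplies the muscle's nominal ref100 threshold (its reference-lift
    amplitude).  ``n_epochs`` consecutive epochs share the episode.
    """

    start_s: float
    muscles: tuple[str, ...]
    intensity: float = 1.5
    forward_deg: float = 0.0
    sideways_deg: float = 0.0
    n_epochs: int = 1


@dataclass
class DayScenario:
    """Ground-truth description of one synthetic measurement day."""

    duration_s: float = 7200.0
    muscles: tuple[str, ...] = MUSCLES
    baseline_rms_mv: dict[str, float] | float = 0.015
    ref_rms_mv: dict[str, float] | float = 0.12
    mve_mv: dict[str, float] | float = 0.6
    events: list[DayEvent] = field(default_factory=list)
    seed: int = 0
    afternoon_calibration: bool = True
    imu_offset_s: float = 3.2
    imu_drift_ppm: float = 20.0
    walking_every_s: float = 600.0
    walking_duration_s: float = 60.0
    hr_baseline_bpm: float = 92.0
    accel_noise_g: float = 0.02
    gyro_noise_dps: float = 1.0

    def per_muscle(self, value) -> dict[str, float]:
        if isinstance(value, dict):
            return {m: float(value[m]) for m in self.muscles}
        return {m: float(value) for m in self.muscles}

    def validate(self) -> None:
        base = self.per_muscle(self.baseline_rms_mv)
        ref = self.per_muscle(self.ref_rms_mv)
        mve = self.per_muscle(self.mve_mv)
        for m in self.muscles:
            if not (0 < base[m] < ref[m] <= mve[m]):
                raise ScenarioError(
                    f"{m}: need 0 < baseline ({base[m]}) < ref ({ref[m]}) <= mve ({mve[m]})"
                )
        used: set[int] = set()
        for ev in self.events:
            if ev.intensity <= 0:
                raise ScenarioError(f"event at {ev.start_s}: intensity must be > 0")
            if ev.start_s % EPOCH_S != 0:
                raise ScenarioError(f"event at {ev.start_s}: not aligned to the {EPOCH_S}-s grid")
            if ev.start_s < 0 or ev.start_s + ev.n_epochs * EPOCH_S > self.duration_s:
                raise ScenarioError(f"event at {ev.start_s}: outside working time")
            unknown = set(ev.muscles) - set(self.muscles)
            if unknown:
                raise ScenarioError(f"event at {ev.start_s}: unknown muscles {unknown}")
            for k in range(ev.n_epochs):
                idx = int(ev.start_s // EPOCH_S) + k
                if idx in used:
                    raise ScenarioError(f"overlapping events at epoch {idx}")
                used.add(idx)


@dataclass
class SyntheticDay:
    """Output bundle of :func:`generate_day`."""

    emg: SignalRecording
    imu_back: SignalRecording
    imu_thigh: SignalRecording
    heart: SignalRecording
    annotations: list[SegmentAnnotation]
    ground_truth: pd.DataFrame
    work_interval: tuple[float, float]
    sync_emg_s: tuple[float, float]
    true_steps: int
    scenario: DayScenario


def _bandlimited_carrier(n: int, fs: float, rng: np.random.Generator,
                         band: tuple[float, float] = (20.0, 450.0)) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to the sEMG band."""
    x = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, x)
    return x / np.std(x)


def _nominal_thresholds(s: DayScenario) -> dict[str, dict[str, float]]:
    ref = s.per_muscle(s.ref_rms_mv)
    mve = s.per_muscle(s.mve_mv)
    return {
        "ref100": dict(ref),
        "ref150": {m: 1.5 * ref[m] for m in s.muscles},
        "mvc50": {m: 0.5 * mve[m] for m in s.muscles},
    }


def _truth_label(s: DayScenario, ev: DayEvent, mode: str) -> bool:
    """Apply the event definition to an episode's nominal amplitudes."""
    from ergoload.events import modified_threshold

    base = s.per_muscle(s.baseline_rms_mv)
    ref = s.per_muscle(s.ref_rms_mv)
    th = _nominal_thresholds(s)[mode]
    amp = {m: (ev.intensity * ref[m] if m in ev.muscles else base[m]) for m in s.muscles}
    n_over = sum(1 for m in s.muscles if amp[m] > th[m])
    if n_over >= 2:
        return True
    for m in ("ESR", "ESL"):
        if m in s.muscles and amp[m] > modified_threshold(th[m], ev.forward_deg, ev.sideways_deg):
            return True
    return False


def generate_day(s: DayScenario) -> SyntheticDay:
    """Render a full synthetic measurement day for a validated scenario.

    Deterministic given the scenario (including its seed).  The returned
    ground-truth table lists every scripted episode epoch with the event
    label it satisfies by construction under each threshold mode.
    """
    s.validate()
    rng = np.random.default_rng(s.seed)
    base = s.per_muscle(s.baseline_rms_mv)
    ref = s.per_muscle(s.ref_rms_mv)
    mve = s.per_muscle(s.mve_mv)

    # ---- protocol timeline on the EMG clock --------------------------------
    annotations: list[SegmentAnnotation] = []
    t = PRE_IDLE
    sync1 = t
    annotations.append(SegmentAnnotation("sync", sync1, sync1 + SYNC_PULSE_S, "morning"))
    t = sync1 + 10.0

    def add_calibration(session: str, t: float) -> float:
        for kind in ("mvc_trapezius", "mvc_erector"):
            for trial in range(3):
                seg = SegmentAnnotation(kind, t, t + MVC_RAMP_S + MVC_HOLD_S, session, trial)
                annotations.append(seg)
                t = seg.end_s + MVC_REST_S
        seg = SegmentAnnotation("reference_lift", t, t + N_LIFTS * LIFT_CYCLE_S, session)
        annotations.append(seg)
        t = seg.end_s + 5.0
        return t

    t = add_calibration("morning", t)
    npose = SegmentAnnotation("npose", t, t + NPOSE_S, "morning")
    annotations.append(npose)
    t = npose.end_s + 5.0
    work = SegmentAnnotation("work", t, t + s.duration_s, "morning")
    annotations.append(work)
    t = work.end_s + 5.0
    if s.afternoon_calibration:
        t = add_calibration("afternoon", t)
    sync2 = t + 5.0
    annotations.append(SegmentAnnotation("sync", sync2, sync2 + SYNC_PULSE_S, "afternoon"))
    total_s = sync2 + 10.0

    # ---- sEMG envelopes ----------------------------------------------------
    n_emg = int(round(total_s * EMG_FS))
    t_emg = np.arange(n_emg) / EMG_FS
    env = {m: np.full(n_emg, base[m]) for m in s.muscles}

    def fill(mask_start: float, mask_end: float, muscle: str, level: np.ndarray | float) -> None:
        i0, i1 = int(round(mask_start * EMG_FS)), int(round(mask_end * EMG_FS))
        env[muscle][i0:i1] = level

    group_of = {"mvc_trapezius": ("TrpR", "TrpL"), "mvc_erector": ("ESR", "ESL")}
    for seg in annotations:
        if seg.kind in group_of:
            n_ramp = int(round(MVC_RAMP_S * EMG_FS))
            n_hold = int(round(MVC_HOLD_S * EMG_FS))
            i0 = int(round(seg.start_s * EMG_FS))
            for m in group_of[seg.kind]:
                if m not in s.muscles:
                    continue
                env[m][i0 : i0 + n_ramp] = np.linspace(base[m], mve[m], n_ramp, endpoint=False)
                env[m][i0 + n_ramp : i0 + n_ramp + n_hold] = mve[m]
        elif seg.kind == "reference_lift":
            for k in range(N_LIFTS):
                c0 = seg.start_s + k * LIFT_CYCLE_S
                for m in s.muscles:
                    fill(c0, c0 + LIFT_ACTIVE_S, m, ref[m])
    for ev in s.events:
        e0 = work.start_s + ev.start_s
        e1 = e0 + ev.n_epochs * EPOCH_S
        for m in ev.muscles:
            fill(e0, e1, m, ev.intensity * ref[m])

    emg_data = np.empty((n_emg, len(s.muscles) + 1))
    for j, m in enumerate(s.muscles):
        emg_data[:, j] = _bandlimited_carrier(n_emg, EMG_FS, rng) * env[m]
    trig = np.zeros(n_emg)
    for t_sync in (sync1, sync2):
        i0 = int(round(t_sync * EMG_FS))
        trig[i0 : i0 + int(round(SYNC_PULSE_S * EMG_FS))] = 2.0
    emg_data[:, -1] = trig
    emg = SignalRecording(
        channels=list(s.muscles) + ["trig"],
        data=emg_data,
        fs=EMG_FS,
        site="emg_torso",
        units={**{m: "mV" for m in s.muscles}, "trig": "mV"},
    )

    # ---- inclination trace on the EMG clock --------------------------------
    # piecewise-constant (fwd, side) angles: zero outside event epochs
    edges = [0.0]
    fwd_levels = [0.0]
    side_levels = [0.0]
    for ev in sorted(s.events, key=lambda e: e.start_s):
        if ev.forward_deg == 0 and ev.sideways_deg == 0:
            continue
        e0 = work.start_s + ev.start_s
        e1 = e0 + ev.n_epochs * EPOCH_S
        edges += [e0, e1]
        fwd_levels += [ev.forward_deg, 0.0]
        side_levels += [ev.sideways_deg, 0.0]

    def angles_at(emg_times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = np.searchsorted(np.asarray(edges), emg_times, side="right") - 1
        return np.asarray(fwd_levels)[idx], np.asarray(side_levels)[idx]

    # ---- IMU streams on their own (offset + drifting) clock ----------------
    def to_stream(emg_t: float | np.ndarray) -> np.ndarray:
        return emg_t + s.imu_offset_s + s.imu_drift_ppm * 1e-6 * (np.asarray(emg_t) - sync1)

    def to_emg(stream_t: np.ndarray) -> np.ndarray:
        d = s.imu_drift_ppm * 1e-6
        return (stream_t - s.imu_offset_s + d * sync1) / (1.0 + d)

    n_imu = int(round((total_s + abs(s.imu_offset_s) + 5.0) * IMU_FS))
    t_imu = np.arange(n_imu) / IMU_FS  # stream clock
    emg_times_of_imu = to_emg(t_imu)
    fwd, side = angles_at(emg_times_of_imu)
    tf, ts_ = np.tan(np.radians(fwd)), np.tan(np.radians(side))
    az = 1.0 / np.sqrt(1.0 + tf**2 + ts_**2)
    ay = tf * az
    ax = -ts_ * az
    accel = np.stack([ax, ay, az], axis=1) + rng.normal(0, s.accel_noise_g, (n_imu, 3))
    gyro = rng.normal(0, s.gyro_noise_dps, (n_imu, 3))
    for t_sync in (sync1, sync2):
        i0 = int(round(float(to_stream(t_sync)) * IMU_FS))
        n_rot = int(round(ROTATION_S * IMU_FS))
        gyro[i0 : i0 + n_rot, 0] += ROTATION_DEG / ROTATION_S
    imu_back = SignalRecording(
        channels=["ax", "ay", "az", "gx", "gy", "gz"],
        data=np.concatenate([accel, gyro], axis=1),
        fs=IMU_FS,
        site="imu_back",
        units={c: ("g" if c.startswith("a") else "deg/s") for c in ("ax", "ay", "az", "gx", "gy", "gz")},
    )

    # thigh: gravity + gait impacts during walking intervals inside work
    accel_t = np.zeros((n_imu, 3))
    accel_t[:, 2] = 1.0
    walk_s = 0.0
    if s.walking_every_s > 0 and s.walking_duration_s > 0:
        w0 = work.start_s
        while w0 + s.walking_duration_s <= work.end_s:
            t0s, t1s = float(to_stream(w0)), float(to_stream(w0 + s.walking_duration_s))
            step_times = np.arange(t0s, t1s, 0.5)  # 2 Hz cadence
            for st in step_times:
                i0 = int(round(st * IMU_FS))
                n_pulse = int(round(0.1 * IMU_FS))
                if i0 + n_pulse < n_imu:
                    pulse = 1.5 * np.hanning(n_pulse)
                    accel_t[i0 : i0 + n_pulse, 2] += pulse
            walk_s += s.walking_duration_s
            w0 += s.walking_every_s
    true_steps = int(round(2.0 * walk_s))
    accel_t += rng.normal(0, s.accel_noise_g, (n_imu, 3))
    gyro_t = rng.normal(0, s.gyro_noise_dps, (n_imu, 3))
    for t_sync in (sync1, sync2):
        i0 = int(round(float(to_stream(t_sync)) * IMU_FS))
        n_rot = int(round(ROTATION_S * IMU_FS))
        gyro_t[i0 : i0 + n_rot, 0] += ROTATION_DEG / ROTATION_S
    imu_thigh = SignalRecording(
        channels=["ax", "ay", "az", "gx", "gy", "gz"],
        data=np.concatenate([accel_t, gyro_t], axis=1),
        fs=IMU_FS,
        site="imu_thigh",
        units={c: ("g" if c.startswith("a") else "deg/s") for c in ("ax", "ay", "az", "gx", "gy", "gz")},
    )

    # ---- heart rate (bpm series on the EMG clock) --------------------------
    n_hr = int(round(total_s * HR_FS))
    t_hr = np.arange(n_hr) / HR_FS
    load = np.zeros(n_hr)
    for ev in s.events:
        e0 = work.start_s + ev.start_s
        i0, i1 = int(round(e0 * HR_FS)), int(round((e0 + ev.n_epochs * EPOCH_S) * HR_FS))
        load[i0:i1] = min(ev.intensity, 2.0)
    hr = s.hr_baseline_bpm + 12.0 * load + rng.normal(0, 2.0, n_hr)
    hr = np.clip(hr, 40.0, 200.0)
    heart = SignalRecording(
        channels=["hr"], data=hr[:, None], fs=HR_FS, site="heart", units={"hr": "bpm"}
    )

    # ---- ground truth ------------------------------------------------------
    rows = []
    for ev in sorted(s.events, key=lambda e: e.start_s):
        for k in range(ev.n_epochs):
            rows.append(
                {
                    "epoch_start_s": work.start_s + ev.start_s + k * EPOCH_S,
                    "muscles": "+".join(ev.muscles),
                    "intensity": ev.intensity,
                    "forward_deg": ev.forward_deg,
                    "sideways_deg": ev.sideways_deg,
                    **{f"event_{mode}": _truth_label(s, ev, mode) for mode in ("ref100", "ref150", "mvc50")},
                }
            )
    ground_truth = pd.DataFrame(
        rows,
        columns=[
            "epoch_start_s", "muscles", "intensity", "forward_deg", "sideways_deg",
            "event_ref100", "event_ref150", "event_mvc50",
        ],
    )

    return SyntheticDay(
        emg=emg,
        imu_back=imu_back,
        imu_thigh=imu_thigh,
        heart=heart,
        annotations=annotations,
        ground_truth=ground_truth,
        work_interval=(work.start_s, work.end_s),
        sync_emg_s=(sync1, sync2),
        true_steps=true_steps,
        scenario=s,
    )


def default_event_schedule(
    n_events: int,
    duration_s: float,
    intensity: float = 1.5,
    rng: np.random.Generator | None = None,
) -> list[DayEvent]:
    """Disjoint single-epoch two-muscle episodes spread over the work interval.

    Alternates neck/shoulder (both trapezius) and low-back (both erector
    spinae) episodes; every third low-back episode is flexed forward 60
    degrees, exercising the modified-threshold posture path without
    changing the label (two muscles are over threshold regardless).
    """
    n_epochs = int(duration_s // EPOCH_S)
    if n_events > n_epochs // 2:
        raise ScenarioError(f"cannot place {n_events} disjoint events in {n_epochs} epochs")
    rng = rng or np.random.default_rng(0)
    slots = np.sort(rng.choice(n_epochs // 2, size=n_events, replace=False)) * 2
    events = []
    for i, slot in enumerate(slots):
        if i % 2 == 0:
            muscles = ("TrpR", "TrpL")
            fwd = 0.0
        else:
            muscles = ("ESR", "ESL")
            fwd = 60.0 if i % 6 == 1 else 0.0
        events.append(
            DayEvent(start_s=float(slot) * EPOCH_S, muscles=muscles, intensity=intensity, forward_deg=fwd)
        )
    return events


# --------------------------------------------------------------------------
# trial-level simulation
# --------------------------------------------------------------------------

TIME_POINTS = ("baseline", "fu1", "fu2")


@dataclass
class TrialScenario:
    """Generative description of a two-arm cluster-randomized trial.

    Fixed effects act on the natural-log event count:
    ``intercept + time effects + arm effect + arm-by-time interaction`` plus
    optional linear covariate effects.  Random structure: cluster intercept
    (construction gang), subject intercept nested in cluster, residual.
    """

    n_clusters_per_arm: int = 8
    cluster_size_range: tuple[int, int] = (4, 6)
    beta: dict[str, float] = field(
        default_factory=lambda: {
            "intercept": 5.2,
            "time_fu1": 0.3,
            "time_fu2": 0.5,
            "arm": 0.0,
            "interaction_fu1": 0.0,
            "interaction_fu2": 0.0,
        }
    )
    covariate_beta: dict[str, float] = field(default_factory=dict)
    sd_cluster: float = 0.2
    sd_subject: float = 0.4
    sd_residual: float = 0.5
    dropout: dict[str, float] = field(default_factory=lambda: {"fu1": 0.10, "fu2": 0.20})
    seed: int = 0

    def validate(self) -> None:
        if self.n_clusters_per_arm < 1:
            raise ScenarioError("need at least one cluster per arm")
        lo, hi = self.cluster_size_range
        if not (1 <= lo <= hi):
            raise ScenarioError(f"bad cluster size range {self.cluster_size_range}")
        for sd in (self.sd_cluster, self.sd_subject, self.sd_residual):
            if sd < 0:
                raise ScenarioError("variance components must be >= 0")
        for k, p in self.dropout.items():
            if not 0 <= p <= 1:
                raise ScenarioError(f"dropout probability {k}={p} outside [0, 1]")


def generate_trial(ts: TrialScenario) -> pd.DataFrame:
    """Long-format trial outcome table with known generative parameters.

    Columns: subject, cluster, arm, time, log_events, events, age, gender,
    duration_h, mean_hr_bpm, steps, strength.  Dropout removes follow-up
    rows missing-at-random; baseline rows are always present.
    """
    ts.validate()
    rng = np.random.default_rng(ts.seed)
    b = ts.beta
    rows = []
    sid = 0
    for arm_idx, arm in enumerate(("intervention", "control")):
        for c in range(ts.n_clusters_per_arm):
            cluster = f"{arm[:3]}_g{c:02d}"
            b_cluster = rng.normal(0.0, ts.sd_cluster)
            size = int(rng.integers(ts.cluster_size_range[0], ts.cluster_size_range[1] + 1))
            for _ in range(size):
                sid += 1
                subject = f"s{sid:03d}"
                b_subject = rng.normal(0.0, ts.sd_subject)
                age = float(np.clip(rng.normal(41.0, 11.0), 19, 65))
                strength = float(np.clip(rng.normal(420.0, 90.0), 150, 800))
                for time in TIME_POINTS:
                    if time != "baseline" and rng.random() < ts.dropout.get(time, 0.0):
                        continue
                    duration_h = float(np.clip(rng.normal(6.9, 0.8), 4, 10))
                    mean_hr = float(np.clip(rng.normal(95.0, 8.0), 60, 140))
                    steps = float(np.clip(rng.normal(5500.0, 1000.0), 1000, 12000))
                    is_int = 1.0 if arm == "intervention" else 0.0
                    y = b["intercept"] + b_cluster + b_subject
                    y += b["arm"] * is_int
                    if time == "fu1":
                        y += b["time_fu1"] + b["interaction_fu1"] * is_int
                    elif time == "fu2":
                        y += b["time_fu2"] + b["interaction_fu2"] * is_int
                    cov = {"age": age, "duration_h": duration_h, "mean_hr_bpm": mean_hr,
                           "steps": steps, "strength": strength}
                    for name, coef in ts.covariate_beta.items():
                        y += coef * cov[name]
                    y += rng.normal(0.0, ts.sd_residual)
                    rows.append(
                        {
                            "subject": subject,
                            "cluster": cluster,
                            "arm": arm,
                            "time": time,
                            "log_events": y,
                            "events": int(max(0, round(np.expm1(y)))),
                            "age": age,
                            "gender": "male",
                            "duration_h": duration_h,
                            "mean_hr_bpm": mean_hr,
                            "steps": steps,
                            "strength": strength,
                        }
                    )
    return pd.DataFrame(rows)
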
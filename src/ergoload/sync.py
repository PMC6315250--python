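"""Cross-stream synchronization from hardware landmarks.

The field setup marks a common instant on every stream twice a day (before
mounting the equipment and after the working day): a 2 mV pulse on a spare
EMG channel and a fast ~95 degree solenoid rotation of the IMUs.  Detecting
both landmark kinds and fitting offset (+ linear clock drift between the two
landmarks) maps every stream onto the EMG clock.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ergoload.errors import SyncError
from ergoload.io import SignalRecording

TRIGGER_NOMINAL_MV = 2.0
TRIGGER_DEBOUNCE_S = 1.0
ROTATION_WINDOW_S = 1.0
ROTATION_MIN_DEG = 60.0


@dataclass
class SyncModel:
    """Linear clock map between a stream and the EMG stream.

    stream_time = emg_time + offset_s + drift * (emg_time - t_ref), with
    drift expressed in parts-per-million (``drift_ppm``).  ``residual_s`` is
    the worst absolute residual of the fit at the landmark pairs.
    """

    offset_s: float
    drift_ppm: float = 0.0
    t_ref: float = 0.0
    residual_s: float = 0.0
    n_pairs: int = 0

    def to_stream_time(self, emg_t: np.ndarray | float) -> np.ndarray | float:
        emg_t = np.asarray(emg_t, dtype=float)
        return emg_t + self.offset_s + self.drift_ppm * 1e-6 * (emg_t - self.t_ref)

    def to_emg_time(self, stream_t: np.ndarray | float) -> np.ndarray | float:
        stream_t = np.asarray(stream_t, dtype=float)
        d = self.drift_ppm * 1e-6
        return (stream_t - self.offset_s + d * self.t_ref) / (1.0 + d)


def detect_emg_trigger(
    rec: SignalRecording,
    trigger_channel: str = "trig",
    nominal_mv: float = TRIGGER_NOMINAL_MV,
    debounce_s: float = TRIGGER_DEBOUNCE_S,
) -> list[float]:
    """Onset times (s) of trigger pulses on the EMG logger.

    An onset is an upward crossing of 50 % of the nominal pulse amplitude;
    crossings closer than ``debounce_s`` to the previous onset are ignored.
    Returns an empty list when no pulse is present.
    """
    x = rec.channel(trigger_channel)
    above = x > 0.5 * nominal_mv
    rising = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        rising = np.concatenate([[0], rising])
    onsets: list[float] = []
    last = -np.inf
    for i in rising:
        t = rec.t0 + i / rec.fs
        if t - last >= debounce_s:
            onsets.append(float(t))
            last = t
    return onsets


def detect_imu_rotation(
    rec: SignalRecording,
    gyro_channels: tuple[str, str, str] = ("gx", "gy", "gz"),
    window_s: float = ROTATION_WINDOW_S,
    min_deg: float = ROTATION_MIN_DEG,
) -> list[float]:
    """Times (s) of fast solenoid rotations on an IMU stream.

    Integrates the gyroscope magnitude (deg/s) over a sliding window of
    ``window_s``; a rotation event is the start of a run where the windowed
    displacement exceeds ``min_deg``.  The nominal 95 degree rotation takes
    ~0.2 s, so slow postural drift (the same displacement over tens of
    seconds) stays well below the threshold.
    """
    g = np.stack([rec.channel(c) for c in gyro_channels], axis=1)
    rate = np.linalg.norm(g, axis=1)  # deg/s
    n_win = max(1, int(round(window_s * rec.fs)))
    # windowed integral of |omega| dt via cumulative sum
    cs = np.concatenate([[0.0], np.cumsum(rate)]) / rec.fs
    disp = cs[n_win:] - cs[:-n_win]  # displacement over [i, i+n_win)
    above = disp > min_deg
    if not above.any():
        return []
    starts = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    events: list[float] = []
    last = -np.inf
    for i in starts:
        # refine: the run start marks the first window containing the burst;
        # locate the rotation onset at the leading edge of the peak rate
        j_hi = min(len(rate), i + 2 * n_win)
        j_peak = i + int(np.argmax(rate[i:j_hi]))
        thresh = 0.1 * rate[j_peak]
        j = j_peak
        while j > i and rate[j - 1] > thresh:
            j -= 1
        t = rec.t0 + j / rec.fs
        if t - last >= 2.0 * window_s:
            events.append(float(t))
            last = t
    return events


def fit_sync(emg_landmarks: list[float], stream_landmarks: list[float]) -> SyncModel:
    """Fit the stream -> EMG clock map from matched landmark times.

    Landmarks are matched in chronological order.  One pair gives a pure
    offset; two or more pairs (pre- and post-day synchronization) additionally
    estimate linear drift by least squares.  Raises :class:`SyncError` with
    zero pairs.
    """
    n = min(len(emg_landmarks), len(stream_landmarks))
    if n == 0:
        raise SyncError("no matched landmark pairs between streams")
    e = np.sort(np.asarray(emg_landmarks, dtype=float))[:n]
    s = np.sort(np.asarray(stream_landmarks, dtype=float))[:n]
    t_ref = float(e[0])
    diff = s - e
    if n == 1:
        return SyncModel(offset_s=float(diff[0]), drift_ppm=0.0, t_ref=t_ref, residual_s=0.0, n_pairs=1)
    # diff = offset + d * (e - t_ref)
    slope, offset = np.polyfit(e - t_ref, diff, 1)
    resid = diff - (offset + slope * (e - t_ref))
    return SyncModel(
        offset_s=float(offset),
        drift_ppm=float(slope * 1e6),
        t_ref=t_ref,
        residual_s=float(np.max(np.abs(resid))),
        n_pairs=int(n),
    )
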
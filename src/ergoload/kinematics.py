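"""Trunk inclination, step counting and heart-rate summaries.

Inclination is accelerometer-inclinometry: a 2 Hz low-pass isolates the
gravity component of the upper-back IMU, and the angle of that vector
relative to the gravity direction captured during a standing neutral pose
(N-pose) gives the trunk tilt.  The tilt is decomposed into a forward
(sagittal) and a sideways (frontal) component in the device frame fixed at
N-pose; forward flexion is positive and the sideways angle is reported as a
left/right magnitude, matching the symmetric threshold decay downstream.

The thigh IMU yields a step count (band-passed acceleration-norm peaks) and
the heart-rate stream a mean working-day level — both covariates of the
trial analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from ergoload.errors import CalibrationError
from ergoload.io import SegmentAnnotation, SignalRecording

ACCEL_CHANNELS = ("ax", "ay", "az")
GRAVITY_LP_HZ = 2.0
NORM_VALID_G = (0.7, 1.3)
HR_VALID_BPM = (30.0, 220.0)


@dataclass
class NposeCalibration:
    """Reference orientation captured during the standing N-pose.

    ``gravity_ref`` is the unit mean accelerometer direction over the
    calibration segment.  ``forward_axis`` and ``side_axis`` complete an
    orthonormal device-frame triad: the forward axis is the device's
    anterior axis (the ``ay`` direction by mounting convention, overridable
    via ``forward_hint``) projected onto the plane orthogonal to gravity.
    """

    gravity_ref: np.ndarray
    forward_axis: np.ndarray
    side_axis: np.ndarray
    mean_norm_g: float = 1.0

    def __post_init__(self) -> None:
        self.gravity_ref = np.asarray(self.gravity_ref, dtype=float)
        self.forward_axis = np.asarray(self.forward_axis, dtype=float)
        self.side_axis = np.asarray(self.side_axis, dtype=float)


@dataclass
class InclinationSeries:
    """Per-sample trunk inclination angles (degrees) relative to N-pose."""

    times: np.ndarray
    forward_deg: np.ndarray
    sideways_deg: np.ndarray
    total_deg: np.ndarray
    valid: np.ndarray
    fs: float = 100.0


def calibrate_npose(
    rec: SignalRecording,
    seg: SegmentAnnotation,
    accel_channels: tuple[str, str, str] = ACCEL_CHANNELS,
    forward_hint: tuple[float, float, float] = (0.0, 1.0, 0.0),
) -> NposeCalibration:
    """Gravity reference from the mean accelerometer vector over the N-pose segment.

    Raises :class:`CalibrationError` when the mean accelerometer norm
    deviates from 1 g by more than 0.3 g (movement during calibration).
    """
    sub = rec.slice_seconds(seg.start_s, seg.end_s)
    if sub.n_samples == 0:
        raise CalibrationError("N-pose segment outside the recording")
    a = np.stack([sub.channel(c) for c in accel_channels], axis=1)
    norms = np.linalg.norm(a, axis=1)
    mean_norm = float(np.mean(norms))
    if abs(mean_norm - 1.0) > 0.3:
        raise CalibrationError(
            f"movement during N-pose calibration: mean accelerometer norm {mean_norm:.2f} g"
        )
    g = np.mean(a, axis=0)
    g = g / np.linalg.norm(g)
    h = np.asarray(forward_hint, dtype=float)
    f = h - np.dot(h, g) * g
    nf = np.linalg.norm(f)
    if nf < 1e-6:
        raise CalibrationError("forward hint is parallel to gravity; cannot define sagittal plane")
    f = f / nf
    s = np.cross(g, f)
    return NposeCalibration(gravity_ref=g, forward_axis=f, side_axis=s, mean_norm_g=mean_norm)


def inclination_series(
    rec: SignalRecording,
    cal: NposeCalibration,
    accel_channels: tuple[str, str, str] = ACCEL_CHANNELS,
    lp_hz: float = GRAVITY_LP_HZ,
) -> InclinationSeries:
    """Forward/sideways inclination of the low-pass-filtered gravity vector.

    The total inclination is the angle between the filtered accelerometer
    vector and ``gravity_ref``; its components are
    ``forward = atan2(a . forward_axis, a . gravity_ref)`` and
    ``sideways = |atan2(a . side_axis, a . gravity_ref)|``.  Samples whose
    filtered norm falls outside 0.7-1.3 g are flagged invalid, not dropped.
    """
    a = np.stack([rec.channel(c) for c in accel_channels], axis=1)
    if rec.fs > 2.5 * lp_hz and a.shape[0] > 15:
        sos = sps.butter(2, lp_hz, btype="lowpass", fs=rec.fs, output="sos")
        a = sps.sosfiltfilt(sos, a, axis=0)
    norms = np.linalg.norm(a, axis=1)
    valid = (norms >= NORM_VALID_G[0]) & (norms <= NORM_VALID_G[1])
    a_g = a @ cal.gravity_ref
    a_f = a @ cal.forward_axis
    a_s = a @ cal.side_axis
    with np.errstate(invalid="ignore", divide="ignore"):
        total = np.degrees(np.arccos(np.clip(a_g / np.maximum(norms, 1e-12), -1.0, 1.0)))
    forward = np.degrees(np.arctan2(a_f, a_g))
    sideways = np.abs(np.degrees(np.arctan2(a_s, a_g)))
    return InclinationSeries(
        times=rec.times(),
        forward_deg=forward,
        sideways_deg=sideways,
        total_deg=total,
        valid=valid,
        fs=rec.fs,
    )


def count_steps(
    rec: SignalRecording,
    work_interval: tuple[float, float] | None = None,
    accel_channels: tuple[str, str, str] = ACCEL_CHANNELS,
    band_hz: tuple[float, float] = (0.5, 3.0),
    min_prominence_g: float = 0.2,
    refractory_s: float = 0.3,
) -> tuple[int, float]:
    """Step count and steps/hour from the thigh accelerometer.

    Band-passes the acceleration norm at 0.5-3 Hz (gait band) and counts
    peaks with prominence >= 0.2 g separated by at least 0.3 s.  The rate is
    normalized by the interval length ("adjusted for length of the working
    day").  DC offset on any axis cancels in the band-pass.
    """
    sub = rec if work_interval is None else rec.slice_seconds(*work_interval)
    if sub.n_samples < 10:
        return 0, 0.0
    a = np.stack([sub.channel(c) for c in accel_channels], axis=1)
    norm = np.linalg.norm(a, axis=1)
    sos = sps.butter(2, band_hz, btype="bandpass", fs=sub.fs, output="sos")
    x = sps.sosfiltfilt(sos, norm - np.mean(norm))
    peaks, _ = sps.find_peaks(
        x, prominence=min_prominence_g, distance=max(1, int(round(refractory_s * sub.fs)))
    )
    hours = sub.duration_s / 3600.0
    n = int(len(peaks))
    return n, (n / hours if hours > 0 else 0.0)


def summarize_heart_rate(
    rec: SignalRecording,
    work_interval: tuple[float, float] | None = None,
    hr_channel: str = "hr",
    valid_bpm: tuple[float, float] = HR_VALID_BPM,
) -> dict:
    """Mean working-day heart rate in bpm over physiologically valid samples.

    Samples outside 30-220 bpm are excluded; the excluded fraction is
    reported, with a quality flag when it exceeds 50 %.
    """
    sub = rec if work_interval is None else rec.slice_seconds(*work_interval)
    x = sub.channel(hr_channel)
    mask = (x >= valid_bpm[0]) & (x <= valid_bpm[1]) & sub.channel_valid(hr_channel)
    frac_excluded = 1.0 - (np.mean(mask) if len(x) else 0.0)
    mean_bpm = float(np.mean(x[mask])) if mask.any() else float("nan")
    return {
        "mean_bpm": mean_bpm,
        "fraction_excluded": float(frac_excluded),
        "quality_warning": bool(frac_excluded > 0.5),
    }
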
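"""sEMG conditioning, RMS amplitude, and event-threshold calibration.

Amplitude processing follows the standard occupational-sEMG chain: zero-phase
band-pass filtering, RMS over 500 ms windows with 20 % overlap, then two
normalization anchors per muscle:

* **MVE** — maximum voluntary electrical activity, the largest RMS window
  observed across up to three maximal voluntary contraction (MVC) trials;
* **reference-lift P90** — the 90th percentile of RMS during a standardized
  20 kg floor-to-table lift task.

Event thresholds come in three modes: ``ref100`` (mean of the morning and
afternoon reference-lift P90), ``ref150`` (1.5 x ref100) and ``mvc50``
(50 % of the mean session MVE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from ergoload.errors import CalibrationError, ConfigurationError
from ergoload.io import SignalRecording

RMS_WINDOW_S = 0.5
RMS_OVERLAP_FRAC = 0.2
THRESHOLD_MODES = ("ref100", "ref150", "mvc50")


@dataclass
class RmsSeries:
    """Windowed RMS amplitudes (mV) with window start times (s)."""

    values: np.ndarray
    times: np.ndarray
    window_s: float = RMS_WINDOW_S
    step_s: float = RMS_WINDOW_S * (1 - RMS_OVERLAP_FRAC)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != self.times.shape:
            raise ValueError("values and times must have the same length")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def max(self) -> float:
        if len(self.values) == 0:
            raise CalibrationError("empty RMS series has no maximum")
        return float(np.max(self.values))


@dataclass
class MuscleThresholds:
    """Per-muscle calibration anchors and base event thresholds.

    ``mve_mv`` and ``ref_p90_mv`` (per session) are the raw anchors;
    ``base`` maps mode -> muscle -> threshold in mV.  ``single_session``
    flags muscles whose calibration used only one session (field days can
    end before the afternoon calibration).
    """

    muscles: list[str]
    mve_mv: dict[str, float]
    ref_p90_mv: dict[str, dict[str, float]]  # muscle -> session -> P90
    base: dict[str, dict[str, float]] = field(default_factory=dict)
    single_session: dict[str, bool] = field(default_factory=dict)

    def threshold(self, mode: str, muscle: str) -> float:
        if mode not in self.base:
            raise ConfigurationError(f"unknown threshold mode {mode!r}")
        if muscle not in self.base[mode]:
            raise ConfigurationError(f"no {mode} threshold for muscle {muscle!r}")
        return self.base[mode][muscle]

    def to_dict(self) -> dict:
        return {
            "muscles": self.muscles,
            "mve_mv": self.mve_mv,
            "ref_p90_mv": self.ref_p90_mv,
            "base": self.base,
            "single_session": self.single_session,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MuscleThresholds":
        return cls(
            muscles=list(d["muscles"]),
            mve_mv=dict(d["mve_mv"]),
            ref_p90_mv={m: dict(v) for m, v in d["ref_p90_mv"].items()},
            base={m: dict(v) for m, v in d["base"].items()},
            single_session=dict(d.get("single_session", {})),
        )


@dataclass
class CalibrationSet:
    """Per-session calibration RMS material for one measurement day.

    ``mvc`` maps session -> muscle -> list of per-trial :class:`RmsSeries`;
    ``reference`` maps session -> muscle -> RMS series over the annotated
    reference-lift segment.
    """

    muscles: list[str]
    mvc: dict[str, dict[str, list[RmsSeries]]]
    reference: dict[str, dict[str, RmsSeries]]


def preprocess_emg(
    rec: SignalRecording,
    band_hz: tuple[float, float] = (10.0, 500.0),
    order: int = 4,
    notch_hz: float | None = None,
    channels: list[str] | None = None,
) -> SignalRecording:
    """Zero-phase band-pass (and optional mains notch) on EMG channels.

    A 4th-order Butterworth applied forward-backward removes offset and
    motion artifact below 10 Hz and noise above 500 Hz.  Channels not listed
    in ``channels`` (e.g. the trigger line) pass through untouched.
    Raises :class:`ConfigurationError` when the sampling rate cannot support
    the upper band edge.
    """
    lo, hi = band_hz
    nyq = rec.fs / 2.0
    if hi >= nyq:
        raise ConfigurationError(
            f"band edge {hi} Hz requires fs > {2 * hi} Hz, got fs={rec.fs}"
        )
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    out = rec.data.copy()
    todo = channels if channels is not None else rec.channels
    for label in todo:
        idx = rec.channels.index(label)
        x = out[:, idx] - np.mean(out[:, idx])
        x = sps.sosfiltfilt(sos, x)
        if notch_hz is not None:
            b, a = sps.iirnotch(notch_hz, Q=30.0, fs=rec.fs)
            x = sps.filtfilt(b, a, x)
        out[:, idx] = x
    return SignalRecording(
        channels=list(rec.channels),
        data=out,
        fs=rec.fs,
        site=rec.site,
        t0=rec.t0,
        units=dict(rec.units),
        valid=rec.valid.copy(),
    )


def rms_windows(
    x: np.ndarray,
    fs: float,
    window_s: float = RMS_WINDOW_S,
    overlap_frac: float = RMS_OVERLAP_FRAC,
    t0: float = 0.0,
) -> RmsSeries:
    """RMS over sliding windows (500 ms, 20 % overlap by default).

    The step is ``round((1 - overlap_frac) * window_s * fs)`` samples
    (410 at 1024 Hz); a trailing partial window is discarded.  An empty or
    too-short signal yields an empty series.
    """
    x = np.asarray(x, dtype=float)
    n_win = int(round(window_s * fs))
    if n_win < 2:
        raise ConfigurationError(f"window of {window_s} s at fs={fs} has < 2 samples")
    step = int(round((1.0 - overlap_frac) * window_s * fs))
    step = max(1, step)
    n = len(x)
    if n < n_win:
        return RmsSeries(values=np.empty(0), times=np.empty(0), window_s=window_s, step_s=step / fs)
    starts = np.arange(0, n - n_win + 1, step)
    sq = np.concatenate([[0.0], np.cumsum(x * x)])
    vals = np.sqrt((sq[starts + n_win] - sq[starts]) / n_win)
    return RmsSeries(values=vals, times=t0 + starts / fs, window_s=window_s, step_s=step / fs)


def mve_from_mvc(trials: list[RmsSeries]) -> float:
    """Maximum voluntary electrical activity: the largest RMS window across trials."""
    if not trials:
        raise CalibrationError("no MVC trials supplied")
    maxima = [t.max for t in trials if len(t) > 0]
    if not maxima:
        raise CalibrationError("all MVC trials produced empty RMS series")
    return float(max(maxima))


def reference_threshold(lift_rms: RmsSeries) -> float:
    """90th percentile (linear-interpolation quantile) of reference-lift RMS."""
    if len(lift_rms) == 0:
        raise CalibrationError("empty reference-lift RMS series")
    return float(np.percentile(lift_rms.values, 90))


def build_thresholds(cal: CalibrationSet) -> MuscleThresholds:
    """Derive per-muscle base event thresholds from a calibration set.

    ref100 averages the per-session reference-lift P90s (morning and
    afternoon when both exist); ref150 = 1.5 x ref100; mvc50 = 0.5 x mean
    session MVE.  A muscle with only one calibrated session is used as-is
    and flagged.  Raises :class:`CalibrationError` naming any muscle with no
    calibration data at all.
    """
    mve: dict[str, float] = {}
    ref_p90: dict[str, dict[str, float]] = {}
    single: dict[str, bool] = {}
    base: dict[str, dict[str, float]] = {m: {} for m in THRESHOLD_MODES}
    for muscle in cal.muscles:
        session_mves = []
        session_p90s: dict[str, float] = {}
        for session, per_muscle in cal.mvc.items():
            trials = per_muscle.get(muscle, [])
            if trials:
                session_mves.append(mve_from_mvc(trials))
        for session, per_muscle in cal.reference.items():
            series = per_muscle.get(muscle)
            if series is not None and len(series) > 0:
                session_p90s[session] = reference_threshold(series)
        if not session_mves or not session_p90s:
            raise CalibrationError(f"no calibration data for muscle {muscle!r}")
        mve[muscle] = float(np.mean(session_mves))
        ref_p90[muscle] = session_p90s
        single[muscle] = len(session_p90s) < 2 or len(session_mves) < 2
        ref100 = float(np.mean(list(session_p90s.values())))
        base["ref100"][muscle] = ref100
        base["ref150"][muscle] = 1.5 * ref100
        base["mvc50"][muscle] = 0.5 * mve[muscle]
    return MuscleThresholds(
        muscles=list(cal.muscles),
        mve_mv=mve,
        ref_p90_mv=ref_p90,
        base=base,
        single_session=single,
    )


def calibration_from_recording(
    rec: SignalRecording,
    segments,
    muscles: list[str],
) -> CalibrationSet:
    """Extract per-session calibration RMS material from an annotated EMG recording.

    MVC segments of kind ``mvc_trapezius`` feed the trapezius channels and
    ``mvc_erector`` the erector spinae channels; ``reference_lift`` segments
    feed every muscle.  The recording should already be preprocessed.
    """
    from ergoload.io import segments_of

    mvc: dict[str, dict[str, list[RmsSeries]]] = {}
    reference: dict[str, dict[str, RmsSeries]] = {}
    group_of = {
        "mvc_trapezius": [m for m in muscles if m.lower().startswith("trp")],
        "mvc_erector": [m for m in muscles if m.lower().startswith("es")],
    }
    sessions = sorted({s.session for s in segments})
    for session in sessions:
        for kind, group in group_of.items():
            for seg in segments_of(segments, kind, session):
                sub = rec.slice_seconds(seg.start_s, seg.end_s)
                for muscle in group:
                    series = rms_windows(sub.channel(muscle), sub.fs, t0=sub.t0)
                    mvc.setdefault(session, {}).setdefault(muscle, []).append(series)
        for seg in segments_of(segments, "reference_lift", session):
            sub = rec.slice_seconds(seg.start_s, seg.end_s)
            for muscle in muscles:
                series = rms_windows(sub.channel(muscle), sub.fs, t0=sub.t0)
                reference.setdefault(session, {})[muscle] = series
    return CalibrationSet(muscles=list(muscles), mvc=mvc, reference=reference)
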
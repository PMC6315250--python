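"""Recording data model and on-disk format.

A recording is stored as delimited text (one column per channel, one row per
sample) next to a JSON sidecar declaring sampling rate, units, channel labels
and body site.  Segment annotations (MVC trials, reference lifts, N-pose,
sync windows, working time) live in one JSON file per session.  All times are
seconds; segment intervals are half-open ``[start_s, end_s)`` on the clock of
the stream they annotate (the EMG clock once synchronized).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ergoload.errors import FormatError

SITES = ("emg_torso", "imu_back", "imu_thigh", "heart")
SEGMENT_KINDS = ("mvc_trapezius", "mvc_erector", "reference_lift", "npose", "sync", "work")


@dataclass
class SignalRecording:
    """A uniformly sampled multi-channel time series.

    Parameters
    ----------
    channels : list of str
        Unique channel labels (e.g. ``["TrpR", "TrpL", "ESR", "ESL", "trig"]``).
    data : ndarray, shape (n_samples, n_channels)
        EMG in mV, acceleration in g, angular rate in deg/s, heart rate in bpm.
    fs : float
        Sampling rate in Hz (> 0).
    site : str
        One of ``emg_torso``, ``imu_back``, ``imu_thigh``, ``heart``.
    t0 : float
        Recording-local start time in seconds.
    units : dict, optional
        Channel label -> unit string.
    valid : ndarray of bool, optional
        Per-sample validity mask (same shape as ``data``); non-finite samples
        are replaced by 0 and flagged invalid at construction.
    """

    channels: list[str]
    data: np.ndarray
    fs: float
    site: str
    t0: float = 0.0
    units: dict[str, str] = field(default_factory=dict)
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[1] != len(self.channels):
            raise FormatError(
                f"data has {self.data.shape[1]} columns but {len(self.channels)} channel labels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise FormatError("channel labels must be unique")
        if not self.fs > 0:
            raise FormatError(f"sampling rate must be positive, got {self.fs}")
        if self.site not in SITES:
            raise FormatError(f"unknown site {self.site!r}; expected one of {SITES}")
        finite = np.isfinite(self.data)
        if self.valid is None:
            self.valid = finite
        else:
            self.valid = np.asarray(self.valid, dtype=bool) & finite
        if not finite.all():
            self.data = np.where(finite, self.data, 0.0)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Per-sample times on the recording-local clock."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in {self.channels}") from None
        return self.data[:, idx]

    def channel_valid(self, label: str) -> np.ndarray:
        idx = self.channels.index(label)
        return self.valid[:, idx]

    def slice_seconds(self, start_s: float, end_s: float) -> "SignalRecording":
        """Sub-recording covering the half-open interval [start_s, end_s)."""
        i0 = max(0, int(np.ceil((start_s - self.t0) * self.fs - 1e-9)))
        i1 = min(self.n_samples, int(np.ceil((end_s - self.t0) * self.fs - 1e-9)))
        return SignalRecording(
            channels=list(self.channels),
            data=self.data[i0:i1].copy(),
            fs=self.fs,
            site=self.site,
            t0=self.t0 + i0 / self.fs,
            units=dict(self.units),
            valid=self.valid[i0:i1].copy(),
        )


@dataclass
class SegmentAnnotation:
    """One annotated interval of a measurement session."""

    kind: str
    start_s: float
    end_s: float
    session: str = "morning"
    trial_index: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise FormatError(f"unknown segment kind {self.kind!r}")
        if not self.end_s > self.start_s:
            raise FormatError(f"segment end {self.end_s} must exceed start {self.start_s}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


REQUIRED_SIDECAR_FIELDS = ("fs", "channels", "units", "site")


def write_recording(
    rec: SignalRecording,
    path: str | Path,
    sidecar: str | Path | None = None,
    fmt: str = "%.17g",
) -> None:
    """Write a recording as delimited text plus a JSON sidecar.

    ``sidecar`` defaults to ``<path>.json``.  The default ``fmt`` keeps
    enough digits for float64 round-trip; pass e.g. ``"%.6g"`` for compact
    archive files.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(path.suffix + ".json")
    np.savetxt(path, rec.data, delimiter="\t", fmt=fmt)
    meta = {
        "fs": rec.fs,
        "channels": rec.channels,
        "units": rec.units,
        "site": rec.site,
        "t0": rec.t0,
    }
    sidecar.write_text(json.dumps(meta, indent=1))


def read_recording(path: str | Path, sidecar: str | Path | None = None) -> SignalRecording:
    """Read a recording written by :func:`write_recording`.

    Non-finite samples are replaced by 0 and flagged in the validity mask.
    Raises :class:`FormatError` when the sidecar is missing required fields or
    declares a non-positive sampling rate.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(path.suffix + ".json")
    if not path.exists():
        raise FormatError(f"signal file not found: {path}")
    if not sidecar.exists():
        raise FormatError(f"sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    missing = [k for k in REQUIRED_SIDECAR_FIELDS if k not in meta]
    if missing:
        raise FormatError(f"sidecar {sidecar} missing fields: {missing}")
    fs = float(meta["fs"])
    if fs <= 0:
        raise FormatError(f"sidecar declares non-positive fs={fs}")
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    return SignalRecording(
        channels=list(meta["channels"]),
        data=data,
        fs=fs,
        site=meta["site"],
        t0=float(meta.get("t0", 0.0)),
        units=dict(meta["units"]),
    )


def write_annotations(segments: list[SegmentAnnotation], path: str | Path) -> None:
    records = [
        {
            "kind": s.kind,
            "start_s": s.start_s,
            "end_s": s.end_s,
            "session": s.session,
            "trial_index": s.trial_index,
        }
        for s in segments
    ]
    Path(path).write_text(json.dumps(records, indent=1))


def read_annotations(path: str | Path) -> list[SegmentAnnotation]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"annotation file not found: {path}")
    records = json.loads(path.read_text())
    return [SegmentAnnotation(**r) for r in records]


def segments_of(segments: list[SegmentAnnotation], kind: str, session: str | None = None) -> list[SegmentAnnotation]:
    """Filter annotations by kind (and optionally session), ordered by start."""
    out = [s for s in segments if s.kind == kind and (session is None or s.session == session)]
    return sorted(out, key=lambda s: s.start_s)
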
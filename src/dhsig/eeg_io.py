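"""Recording I/O, preprocessing and segmentation into 1-s event vectors.

An *event* is one electrode's samples within one window (1 s by default).
Event rows are ordered window-major overall and electrode-major within each
window: row ``w * n_channels + e`` holds electrode ``e`` in window ``w``.
This convention is frozen; it makes every block of consecutive windows a
contiguous row slice (see :mod:`dhsig.pbdhs`).
"""

from __future__ import annotations

import csv as _csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from dhsig.edf import read_edf, EdfError

__all__ = [
    "Recording",
    "EventMatrix",
    "read_recording",
    "preprocess",
    "segment_events",
    "resample_recording",
    "read_manifest",
    "ANNOTATION_LABELS",
]

# substrings (lower-case) marking non-EEG channels to drop on load
ANNOTATION_LABELS = ("edf annotations", "annotation", "status", "marker", "trigger", "event")


@dataclass
class Recording:
    """A multichannel recording: channels x samples in microvolts."""

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be 2-D (channels x samples)")
        if self.n_channels < 2:
            raise ValueError(f"Recording needs >= 2 channels, got {self.n_channels}")
        if self.fs <= 0:
            raise ValueError(f"Recording.fs must be positive, got {self.fs}")
        if self.n_samples <= self.fs:
            raise ValueError(
                f"Recording needs > 1 s of data: {self.n_samples} samples at fs={self.fs}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Recording contains non-finite samples")
        if not self.channel_labels:
            self.channel_labels = [f"CH{i + 1:02d}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length != number of channels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EventMatrix:
    """Stacked event vectors plus (electrode, window) provenance per row."""

    events: np.ndarray
    index: list[tuple[int, int]]
    fs: float
    window_s: float

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=np.float64)
        if self.events.ndim != 2:
            raise ValueError("events must be 2-D (n_events x window_len)")
        if len(self.index) != self.events.shape[0]:
            raise ValueError("index length != number of event rows")

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    @property
    def n_channels(self) -> int:
        return 1 + max(e for e, _ in self.index)

    @property
    def n_windows(self) -> int:
        return 1 + max(w for _, w in self.index)


def _read_csv_matrix(path: Path) -> np.ndarray:
    """Numeric matrix from CSV, rows = channels; a single header row is allowed."""
    with open(path, newline="") as fh:
        rows = [r for r in _csv.reader(fh) if r]
    if not rows:
        raise ValueError(f"{path}: empty CSV")
    try:
        [float(x) for x in rows[0]]
    except ValueError:
        rows = rows[1:]  # header row
    if not rows:
        raise ValueError(f"{path}: CSV has a header but no data rows")
    try:
        return np.array([[float(x) for x in r] for r in rows], dtype=np.float64)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric CSV cell: {exc}") from exc


def read_recording(
    path: str | Path,
    fmt: str | None = None,
    fs: float = 500.0,
    subject_id: str | None = None,
) -> Recording:
    """Load an EDF or CSV recording.

    ``fmt`` is inferred from the extension when omitted. For CSV (rows =
    channels, optional header) the sampling rate is not stored in the file
    and is taken from ``fs``. Non-EEG annotation channels in EDF files are
    dropped by label blacklist.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording not found: {path}")
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "csv"
    if fmt not in ("edf", "csv"):
        raise ValueError(f"unknown format {fmt!r}; expected 'edf' or 'csv'")

    sid = subject_id if subject_id is not None else path.stem
    if fmt == "edf":
        data, fs_read, labels = read_edf(path)
        keep = [
            i
            for i, lab in enumerate(labels)
            if not any(tag in lab.lower() for tag in ANNOTATION_LABELS)
        ]
        if not keep:
            raise EdfError(f"{path}: no EEG channels left after dropping annotation channels")
        return Recording(
            data=data[keep],
            fs=fs_read,
            channel_labels=[labels[i] for i in keep],
            subject_id=sid,
        )
    data = _read_csv_matrix(path)
    return Recording(data=data, fs=fs, subject_id=sid)


def preprocess(rec: Recording, hp_hz: float = 1.0, notch_hz: float = 50.0) -> Recording:
    """Zero-phase high-pass (``hp_hz``) plus mains notch (``notch_hz``).

    High-pass: 4th-order Butterworth applied forward-backward per channel.
    Notch: IIR notch (Q=30) applied forward-backward. Shape is preserved.
    """
    if rec.fs <= 2 * notch_hz:
        raise ValueError(
            f"fs={rec.fs} too low for a {notch_hz} Hz notch (need fs > {2 * notch_hz})"
        )
    out = rec.data
    if hp_hz and hp_hz > 0:
        sos = sps.butter(4, hp_hz, btype="highpass", fs=rec.fs, output="sos")
        out = sps.sosfiltfilt(sos, out, axis=1)
    if notch_hz and notch_hz > 0:
        b, a = sps.iirnotch(notch_hz, Q=30.0, fs=rec.fs)
        out = sps.filtfilt(b, a, out, axis=1)
    return Recording(
        data=np.ascontiguousarray(out),
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        subject_id=rec.subject_id,
    )


def resample_recording(rec: Recording, target_fs: float = 500.0) -> Recording:
    """Polyphase resample to ``target_fs`` (no-op when already there)."""
    if abs(rec.fs - target_fs) < 1e-9:
        return rec
    from fractions import Fraction

    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    data = sps.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return Recording(
        data=data,
        fs=target_fs,
        channel_labels=list(rec.channel_labels),
        subject_id=rec.subject_id,
    )


def segment_events(
    rec: Recording,
    window_s: float = 1.0,
    total_s: float = 500.0,
    offset_s: float = 0.0,
) -> EventMatrix:
    """Cut each channel into consecutive non-overlapping windows of ``window_s``.

    Returns ``n_channels * (total_s / window_s)`` events starting at
    ``offset_s``. Row order: window-major, electrode-major within a window.
    """
    if window_s <= 0 or total_s <= 0 or offset_s < 0:
        raise ValueError("window_s and total_s must be positive, offset_s nonnegative")
    needed = offset_s + total_s
    if rec.duration_s < needed - 1e-9:
        raise ValueError(
            f"recording too short: need {needed:g} s (offset {offset_s:g} + total {total_s:g}), "
            f"have {rec.duration_s:g} s"
        )
    win_len = int(round(window_s * rec.fs))
    if abs(win_len - window_s * rec.fs) > 1e-6:
        raise ValueError(f"window_s={window_s} x fs={rec.fs} is not an integer sample count")
    n_windows = int(round(total_s / window_s))
    if abs(n_windows - total_s / window_s) > 1e-9:
        raise ValueError(f"total_s={total_s} is not a whole number of {window_s}-s windows")
    start = int(round(offset_s * rec.fs))
    n_ch = rec.n_channels

    seg = rec.data[:, start : start + n_windows * win_len]
    # [ch, win, t] -> [win, ch, t] -> rows
    events = np.ascontiguousarray(
        seg.reshape(n_ch, n_windows, win_len).transpose(1, 0, 2).reshape(-1, win_len)
    )
    index = [(e, w) for w in range(n_windows) for e in range(n_ch)]
    return EventMatrix(events=events, index=index, fs=rec.fs, window_s=window_s)


def read_manifest(path: str | Path) -> list[tuple[Path, str]]:
    """Cohort manifest CSV with columns path,label (header optional)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    out: list[tuple[Path, str]] = []
    with open(path, newline="") as fh:
        for row in _csv.reader(fh):
            if not row or not row[0].strip():
                continue
            if row[0].strip().lower() == "path":
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: manifest row needs path,label: {row}")
            p = Path(row[0].strip())
            if not p.is_absolute():
                p = path.parent / p
            out.append((p, row[1].strip()))
    if not out:
        raise ValueError(f"{path}: empty manifest")
    return out
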
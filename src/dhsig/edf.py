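"""Minimal European Data Format (EDF) reader/writer.

Supports the plain-EDF subset used here: a fixed-length ASCII header,
one int16 little-endian sample stream per signal, uniform sampling rate
per signal, and 1-s data records. Physical units are microvolts.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np

__all__ = ["read_edf", "write_edf", "EdfError"]

_HDR = 256  # bytes of the fixed header; +256 per signal

DIGITAL_MIN = -32768
DIGITAL_MAX = 32767


class EdfError(ValueError):
    """Raised when a file cannot be parsed as EDF."""


def _field(raw: bytes, start: int, width: int) -> str:
    return raw[start : start + width].decode("ascii", errors="replace").strip()


def _pad(value: str, width: int) -> bytes:
    s = value[:width].ljust(width)
    return s.encode("ascii")


def write_edf(
    path: str | Path,
    data: np.ndarray,
    fs: float,
    channel_labels: list[str] | None = None,
    subject_id: str = "X",
    physical_dim: str = "uV",
) -> None:
    """Write a channels-by-samples matrix (physical units) as 16-bit EDF.

    Samples are quantised per channel to the int16 range; the data must
    contain an integer number of 1-s records (``samples % fs == 0``).
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise EdfError("data must be a 2-D channels-by-samples matrix")
    n_channels, n_samples = data.shape
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise EdfError(f"non-integer samples per 1-s record: fs={fs}")
    if n_samples % spr != 0:
        raise EdfError(f"{n_samples} samples is not a whole number of 1-s records at fs={fs}")
    n_records = n_samples // spr
    if channel_labels is None:
        channel_labels = [f"CH{i + 1:02d}" for i in range(n_channels)]
    if len(channel_labels) != n_channels:
        raise EdfError("channel_labels length does not match channel count")

    phys_min = np.floor(np.min(data, axis=1))
    phys_max = np.ceil(np.max(data, axis=1))
    # degenerate (constant) channels still need a nonzero physical span
    flat = phys_max <= phys_min
    phys_min[flat] -= 1.0
    phys_max[flat] += 1.0

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _pad("0", 8),
            _pad(subject_id, 80),
            _pad("Startdate X", 80),
            _pad(now.strftime("%d.%m.%y"), 8),
            _pad(now.strftime("%H.%M.%S"), 8),
            _pad(str(_HDR * (n_channels + 1)), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(n_channels), 4),
        ]
    )
    per_signal = [
        b"".join(_pad(lab, 16) for lab in channel_labels),
        b"".join(_pad("", 80) for _ in range(n_channels)),
        b"".join(_pad(physical_dim, 8) for _ in range(n_channels)),
        b"".join(_pad(f"{phys_min[i]:g}", 8) for i in range(n_channels)),
        b"".join(_pad(f"{phys_max[i]:g}", 8) for i in range(n_channels)),
        b"".join(_pad(str(DIGITAL_MIN), 8) for _ in range(n_channels)),
        b"".join(_pad(str(DIGITAL_MAX), 8) for _ in range(n_channels)),
        b"".join(_pad("", 80) for _ in range(n_channels)),
        b"".join(_pad(str(spr), 8) for _ in range(n_channels)),
        b"".join(_pad("", 32) for _ in range(n_channels)),
    ]

    scale = (phys_max - phys_min) / (DIGITAL_MAX - DIGITAL_MIN)
    digital = np.empty_like(data, dtype=np.int16)
    for i in range(n_channels):
        d = (data[i] - phys_min[i]) / scale[i] + DIGITAL_MIN
        digital[i] = np.clip(np.round(d), DIGITAL_MIN, DIGITAL_MAX).astype(np.int16)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(b"".join(per_signal))
        # record-major layout: all signals' samples for record r, then r+1, ...
        blocks = digital.reshape(n_channels, n_records, spr)
        interleaved = np.ascontiguousarray(blocks.transpose(1, 0, 2))
        fh.write(interleaved.astype("<i2").tobytes())


def read_edf(path: str | Path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file; returns (physical data [channels x samples], fs, labels).

    All signals must share one sampling rate (the only regime produced and
    consumed here); records are assumed contiguous.
    """
    raw = Path(path).read_bytes()
    if len(raw) < _HDR:
        raise EdfError(f"{path}: truncated EDF header")
    try:
        n_records = int(_field(raw, 236, 8))
        record_dur = float(_field(raw, 244, 8))
        ns = int(_field(raw, 252, 4))
    except ValueError as exc:
        raise EdfError(f"{path}: malformed EDF header") from exc
    if ns < 1:
        raise EdfError(f"{path}: no signals declared")
    hdr_len = _HDR * (ns + 1)
    if len(raw) < hdr_len:
        raise EdfError(f"{path}: truncated signal headers")

    def sig_fields(offset: int, width: int) -> list[str]:
        base = _HDR + offset * ns
        return [_field(raw, base + i * width, width) for i in range(ns)]

    # cumulative per-signal byte offsets: label 0, transducer 16, phys-dim 96,
    # phys-min 104, phys-max 112, dig-min 120, dig-max 128, prefilter 136, spr 216
    labels = sig_fields(0, 16)
    phys_min = np.array([float(x) for x in sig_fields(104, 8)])
    phys_max = np.array([float(x) for x in sig_fields(112, 8)])
    dig_min = np.array([float(x) for x in sig_fields(120, 8)])
    dig_max = np.array([float(x) for x in sig_fields(128, 8)])
    spr = [int(x) for x in sig_fields(216, 8)]

    if len(set(spr)) != 1:
        raise EdfError(f"{path}: mixed per-signal sampling rates {sorted(set(spr))} unsupported")
    if record_dur <= 0:
        raise EdfError(f"{path}: non-positive record duration")
    fs = spr[0] / record_dur

    rec_len = sum(spr)
    payload = np.frombuffer(raw, dtype="<i2", offset=hdr_len)
    if n_records < 0:  # -1 means "unknown"; infer from file size
        n_records = payload.size // rec_len
    if payload.size < n_records * rec_len:
        raise EdfError(f"{path}: data shorter than declared {n_records} records")
    payload = payload[: n_records * rec_len].reshape(n_records, ns, spr[0])

    gain = (phys_max - phys_min) / (dig_max - dig_min)
    data = payload.transpose(1, 0, 2).reshape(ns, -1).astype(np.float64)
    data = (data - dig_min[:, None]) * gain[:, None] + phys_min[:, None]
    return data, fs, labels
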
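"""Synthetic multichannel EEG-like recordings and cohorts.

Each channel is a sum of band-limited filtered-noise oscillations (one
component per canonical band, weighted by ``band_weights``), mixed from a
channel-shared and a channel-private source so that the expected pairwise
correlation equals ``coupling``, plus a slow per-channel drift scaled by
``nonstationarity`` and white measurement noise. Not physiological — the
point is controllable inter-channel structure for testing every downstream
stage without data downloads.
"""

from __future__ import annotations

import csv as _csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

from dhsig.edf import write_edf
from dhsig.eeg_io import Recording

__all__ = ["SynthConfig", "generate_recording", "generate_cohort", "save_cohort", "TEN_TWENTY_19"]

# standard 10-20 labels for the 19-electrode montage
TEN_TWENTY_19 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz",
    "C4", "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
]

DEFAULT_BANDS: tuple[tuple[float, float], ...] = (
    (0.5, 4.0),
    (4.0, 8.0),
    (8.0, 12.0),
    (12.0, 30.0),
    (30.0, 100.0),
)


@dataclass
class SynthConfig:
    n_channels: int = 19
    fs: float = 500.0
    duration: float = 500.0
    group_label: str = "synthetic"
    coupling: float = 0.5
    nonstationarity: float = 0.0
    band_weights: tuple[float, ...] = (4.0, 3.0, 6.0, 2.0, 1.0)  # uV per band component
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_channels < 2:
            raise ValueError(f"n_channels must be >= 2, got {self.n_channels}")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-6:
            raise ValueError(f"duration x fs must be an integer sample count, got {n}")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError(f"coupling must lie in [0, 1], got {self.coupling}")
        if self.nonstationarity < 0:
            raise ValueError(f"nonstationarity must be >= 0, got {self.nonstationarity}")
        if len(self.band_weights) != len(DEFAULT_BANDS):
            raise ValueError(
                f"band_weights needs {len(DEFAULT_BANDS)} entries, got {len(self.band_weights)}"
            )
        if any(w < 0 for w in self.band_weights):
            raise ValueError(f"band_weights must be >= 0, got {self.band_weights}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


def _band_noise(
    rng: np.random.Generator, n: int, lo: float, hi: float, fs: float
) -> np.ndarray:
    """Unit-SD noise band-passed to (lo, hi); edges clipped below Nyquist."""
    hi = min(hi, 0.45 * fs)
    if hi <= lo:
        return np.zeros(n)
    x = rng.standard_normal(n)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def generate_recording(cfg: SynthConfig, subject_id: str | None = None) -> Recording:
    """Deterministic synthetic recording for the given config and seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    n_ch = cfg.n_channels

    a_shared = np.sqrt(cfg.coupling)
    a_priv = np.sqrt(1.0 - cfg.coupling)
    data = np.zeros((n_ch, n))
    for (lo, hi), w in zip(DEFAULT_BANDS, cfg.band_weights):
        if w == 0:
            continue
        shared = _band_noise(rng, n, lo, hi, cfg.fs)
        for c in range(n_ch):
            private = _band_noise(rng, n, lo, hi, cfg.fs)
            data[c] += w * (a_shared * shared + a_priv * private)

    if cfg.nonstationarity > 0:
        osc_sd = float(np.sqrt(sum(w * w for w in cfg.band_weights)))
        t = np.arange(n) / cfg.fs
        for c in range(n_ch):
            f_drift = rng.uniform(0.005, 0.03)
            phase = rng.uniform(0, 2 * np.pi)
            data[c] += cfg.nonstationarity * osc_sd * np.sin(2 * np.pi * f_drift * t + phase)

    if cfg.noise_sd > 0:
        data += cfg.noise_sd * rng.standard_normal((n_ch, n))

    labels = TEN_TWENTY_19 if n_ch == 19 else [f"CH{i + 1:02d}" for i in range(n_ch)]
    sid = subject_id if subject_id is not None else f"synth-{cfg.group_label}-{cfg.seed}"
    return Recording(data=data, fs=cfg.fs, channel_labels=list(labels), subject_id=sid)


def _subject_seed(master_seed: int, group_idx: int, subject_idx: int) -> int:
    """Stable per-subject seed derived from (master, group, subject)."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(group_idx, subject_idx))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def generate_cohort(
    group_cfgs: list[tuple[SynthConfig, int]],
    seed: int = 0,
) -> list[tuple[Recording, str]]:
    """Labelled recordings for each (config template, n_subjects) group."""
    if not group_cfgs:
        raise ValueError("empty group list")
    out: list[tuple[Recording, str]] = []
    for gi, (template, n_subjects) in enumerate(group_cfgs):
        if n_subjects < 1:
            raise ValueError(f"group {gi}: n_subjects must be >= 1, got {n_subjects}")
        for si in range(n_subjects):
            cfg = replace(template, seed=_subject_seed(seed, gi, si))
            rec = generate_recording(cfg, subject_id=f"g{gi}s{si:03d}")
            out.append((rec, template.group_label))
    return out


def save_cohort(
    cohort: list[tuple[Recording, str]],
    out_dir: str | Path,
    fmt: str = "edf",
) -> Path:
    """Write recordings (EDF or CSV) plus a path,label manifest; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["path", "label"])
        for rec, label in cohort:
            name = f"{rec.subject_id}.{fmt}"
            path = out_dir / name
            if fmt == "edf":
                write_edf(path, rec.data, rec.fs, rec.channel_labels, subject_id=rec.subject_id)
            elif fmt == "csv":
                np.savetxt(path, rec.data, delimiter=",", fmt="%.6f")
            else:
                raise ValueError(f"unknown cohort format {fmt!r}")
            w.writerow([name, label])
    return manifest
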
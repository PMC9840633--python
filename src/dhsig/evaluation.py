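"""ROC/AUC evaluation, the random-grouping null control, and band power.

AUC is computed by the Mann-Whitney rank identity (ties counted half); the
ROC curve itself is built from cumulative true/false-positive fractions at
descending score thresholds. Orientation is NOT forced above 0.5: ``auc``
is reported raw (positive label = higher score convention) with a
``auc_flipped`` convenience field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.stats import rankdata, norm

from dhsig.eeg_io import Recording

__all__ = [
    "RocResult",
    "roc_auc",
    "mann_whitney_auc",
    "random_grouping_null",
    "band_power",
    "CANONICAL_BANDS",
]

CANONICAL_BANDS: dict[str, tuple[float, float]] = {
    "0.5-4": (0.5, 4.0),
    "4-8": (4.0, 8.0),
    "8-12": (8.0, 12.0),
    "12-30": (12.0, 30.0),
    "30-100": (30.0, 100.0),
}


@dataclass
class RocResult:
    auc: float  # P(score_pos > score_neg) + 0.5 P(equal)
    auc_flipped: float  # 1 - auc
    n_pos: int
    n_neg: int
    curve: np.ndarray  # (k, 2) points: (false-positive frac, true-positive frac)
    p_value: float  # two-sided normal-approximation Mann-Whitney test


def mann_whitney_auc(scores, labels) -> float:
    """Rank-based AUC; ties contribute 1/2. Labels: 1 = positive class."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _roc_curve(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # collapse tied thresholds
    distinct = np.r_[np.diff(s) != 0, True]
    tp = np.cumsum(y == 1)[distinct]
    fp = np.cumsum(y == 0)[distinct]
    tpf = np.r_[0.0, tp / max(tp[-1], 1)]
    fpf = np.r_[0.0, fp / max(fp[-1], 1)]
    return np.column_stack([fpf, tpf])


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and Mann-Whitney AUC for binary labels (1 = positive)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    auc = mann_whitney_auc(scores, labels)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    # normal approximation of the U statistic (no tie correction beyond midranks)
    mu = 0.5
    sigma = np.sqrt((n1 + n0 + 1) / (12.0 * n1 * n0))
    z = (auc - mu) / sigma
    p = float(2 * norm.sf(abs(z)))
    return RocResult(
        auc=auc,
        auc_flipped=1.0 - auc,
        n_pos=n1,
        n_neg=n0,
        curve=_roc_curve(scores, labels),
        p_value=min(p, 1.0),
    )


def random_grouping_null(
    values,
    group_sizes: list[int],
    n_iter: int = 10_000,
    seed: int = 0,
) -> dict[tuple[int, int], tuple[float, float]]:
    """Random-regrouping null: mean and SD of pairwise AUCs over n_iter shuffles.

    Values are partitioned uniformly at random into groups of the given
    sizes each iteration; every unordered group pair gets an AUC (first
    group of the pair taken as positive). Returns {(i, j): (mean, sd)}.
    """
    values = np.asarray(values, dtype=np.float64)
    if sum(group_sizes) != len(values):
        raise ValueError(
            f"group sizes {group_sizes} sum to {sum(group_sizes)}, have {len(values)} values"
        )
    if any(s < 1 for s in group_sizes):
        raise ValueError("all group sizes must be >= 1")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    k = len(group_sizes)
    bounds = np.cumsum([0] + list(group_sizes))
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    aucs = {pair: np.empty(n_iter) for pair in pairs}
    rng = np.random.default_rng(seed)
    for it in range(n_iter):
        perm = rng.permutation(len(values))
        parts = [values[perm[bounds[i] : bounds[i + 1]]] for i in range(k)]
        for i, j in pairs:
            s = np.concatenate([parts[i], parts[j]])
            y = np.r_[np.ones(group_sizes[i]), np.zeros(group_sizes[j])]
            aucs[(i, j)][it] = mann_whitney_auc(s, y)
    return {pair: (float(a.mean()), float(a.std())) for pair, a in aucs.items()}


def band_power(
    rec: Recording,
    bands: dict[str, tuple[float, float]] | None = None,
    nperseg_s: float = 2.0,
) -> dict[str, np.ndarray]:
    """Welch band power per channel: {band: array of integrated power, uV^2}.

    Welch with Hann windows of ``nperseg_s`` seconds and 50% overlap; band
    power is the PSD integrated over the band. Bands reaching above Nyquist
    are truncated with a warning.
    """
    import warnings

    if bands is None:
        bands = CANONICAL_BANDS
    nper = min(int(round(nperseg_s * rec.fs)), rec.n_samples)
    freqs, psd = sps.welch(
        rec.data, fs=rec.fs, window="hann", nperseg=nper, noverlap=nper // 2, axis=1
    )
    nyquist = rec.fs / 2.0
    out: dict[str, np.ndarray] = {}
    for name, (lo, hi) in bands.items():
        if hi > nyquist:
            warnings.warn(
                f"band {name} upper edge {hi} Hz above Nyquist {nyquist} Hz; truncating",
                stacklevel=2,
            )
            hi = nyquist
        mask = (freqs >= lo) & (freqs <= hi)
        if mask.sum() < 2:
            out[name] = psd[:, mask].sum(axis=1) * (freqs[1] - freqs[0])
        else:
            out[name] = np.trapezoid(psd[:, mask], freqs[mask], axis=1)
    return out
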
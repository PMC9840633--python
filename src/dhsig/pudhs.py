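"""Personal universal DH signature (PUDHS).

For one universal dendrogram with maximal 2-adic ball B and a global
natural parameter z, the threshold is T = 2**(B - z) and

    PUDHS = #{ leaves i : V_i < T }   (strict inequality).

Topologically this is the number of sub-dendrograms dissected by the
threshold line. Comparisons are exact integer arithmetic throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd

from dhsig.eeg_io import Recording, preprocess, segment_events
from dhsig.padic import CodedTree, assign_codes, count_below_power
from dhsig.tree import build_tree

__all__ = ["PudhsResult", "compute_pudhs", "pudhs_cohort", "pudhs_for_recording"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PudhsResult:
    z: int
    max_ball: int
    threshold_exponent: int  # T = 2**threshold_exponent, exact
    pudhs: int
    n_leaves: int

    @property
    def threshold(self) -> float:
        return 2.0 ** self.threshold_exponent


def compute_pudhs(coded: CodedTree, z: int) -> PudhsResult:
    """Count branch values strictly below 2**(max_ball - z)."""
    if z < 1:
        raise ValueError(f"z must be a natural number >= 1, got {z}")
    if coded.n_leaves < 2:
        raise ValueError("need >= 2 leaves")
    exponent = coded.max_ball - z
    if exponent < 0:
        warnings.warn(
            f"z={z} exceeds max_ball={coded.max_ball}: threshold < 1, only V=0 counts",
            stacklevel=2,
        )
    count = count_below_power(coded.values(), exponent)
    return PudhsResult(
        z=z,
        max_ball=coded.max_ball,
        threshold_exponent=exponent,
        pudhs=count,
        n_leaves=coded.n_leaves,
    )


def pudhs_for_recording(
    rec: Recording,
    z: int = 4,
    window_s: float = 1.0,
    total_s: float = 500.0,
    offset_s: float = 0.0,
    do_preprocess: bool = True,
) -> PudhsResult:
    """Full single-subject pipeline: preprocess -> segment -> tree -> codes -> PUDHS."""
    if do_preprocess:
        rec = preprocess(rec)
    events = segment_events(rec, window_s=window_s, total_s=total_s, offset_s=offset_s)
    coded = assign_codes(build_tree(events))
    return compute_pudhs(coded, z)


def pudhs_cohort(
    recordings: list[tuple[Recording, str]],
    z: int = 4,
    window_s: float = 1.0,
    total_s: float = 500.0,
    offset_s: float = 0.0,
    do_preprocess: bool = True,
) -> pd.DataFrame:
    """One PUDHS row per subject; per-subject failures are logged and skipped.

    Returns a DataFrame with columns subject, label, z, max_ball,
    threshold_exponent, pudhs, n_leaves plus a ``.attrs['failures']`` list.
    """
    rows = []
    failures: list[tuple[str, str]] = []
    for rec, label in recordings:
        try:
            res = pudhs_for_recording(
                rec,
                z=z,
                window_s=window_s,
                total_s=total_s,
                offset_s=offset_s,
                do_preprocess=do_preprocess,
            )
        except Exception as exc:  # noqa: BLE001 - per-subject isolation is the contract
            logger.warning("subject %s failed: %s", rec.subject_id, exc)
            failures.append((rec.subject_id, str(exc)))
            continue
        rows.append(
            {
                "subject": rec.subject_id,
                "label": label,
                "z": res.z,
                "max_ball": res.max_ball,
                "threshold_exponent": res.threshold_exponent,
                "pudhs": res.pudhs,
                "n_leaves": res.n_leaves,
            }
        )
        logger.info("subject %s: PUDHS=%d (max_ball=%d)", rec.subject_id, res.pudhs, res.max_ball)
    if failures:
        logger.warning("%d subject(s) failed: %s", len(failures), [s for s, _ in failures])
    df = pd.DataFrame(
        rows,
        columns=["subject", "label", "z", "max_ball", "threshold_exponent", "pudhs", "n_leaves"],
    )
    df.attrs["failures"] = failures
    return df
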
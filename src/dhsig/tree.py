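"""Ward dendrograms over event vectors, exposed as explicit binary merge trees.

Linkage uses Ward's minimum-variance criterion on pairwise Euclidean
distances (Lance-Williams update, heights on the distance scale). Heights
never enter the downstream 2-adic signatures — only topology does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from dhsig.eeg_io import EventMatrix

__all__ = ["DendroTree", "pairwise_distances", "build_tree", "to_newick", "linkage_table"]


@dataclass
class DendroTree:
    """Full binary merge tree: leaves ``0..n-1``, internal node ``n+i`` is merge ``i``."""

    n_leaves: int
    merges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        n = self.n_leaves
        if len(self.merges) != n - 1:
            raise ValueError(f"binary tree over {n} leaves needs {n - 1} merges, got {len(self.merges)}")
        seen_parent = np.zeros(2 * n - 1, dtype=bool)
        for i, (a, b, h) in enumerate(self.merges):
            node = n + i
            if not (0 <= a < node and 0 <= b < node) or a == b:
                raise ValueError(f"merge {i} references invalid children ({a}, {b})")
            if seen_parent[a] or seen_parent[b]:
                raise ValueError(f"merge {i}: child already has a parent")
            if h < 0:
                raise ValueError(f"merge {i}: negative height {h}")
            seen_parent[a] = seen_parent[b] = True

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def children(self, node: int) -> tuple[int, int]:
        if node < self.n_leaves:
            raise ValueError(f"node {node} is a leaf")
        a, b, _ = self.merges[node - self.n_leaves]
        return a, b

    def height(self, node: int) -> float:
        if node < self.n_leaves:
            return 0.0
        return self.merges[node - self.n_leaves][2]

    def min_leaf_ids(self) -> np.ndarray:
        """Smallest leaf id under each node (leaves map to themselves)."""
        n = self.n_leaves
        out = np.empty(self.n_nodes, dtype=np.int64)
        out[:n] = np.arange(n)
        for i, (a, b, _) in enumerate(self.merges):
            out[n + i] = min(out[a], out[b])
        return out

    def leaf_sets(self) -> list[frozenset[int]]:
        """Leaf set under each node; O(n^2) — intended for small trees/tests."""
        n = self.n_leaves
        sets: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
        for a, b, _ in self.merges:
            sets.append(sets[a] | sets[b])
        return sets

    @classmethod
    def from_linkage(cls, Z: np.ndarray) -> "DendroTree":
        Z = np.asarray(Z, dtype=np.float64)
        n = Z.shape[0] + 1
        merges = [(int(a), int(b), float(h)) for a, b, h, _ in Z]
        return cls(n_leaves=n, merges=merges)

    def to_linkage(self) -> np.ndarray:
        """SciPy-style (n-1) x 4 linkage matrix (children, height, cluster size)."""
        n = self.n_leaves
        sizes = np.ones(self.n_nodes)
        Z = np.zeros((n - 1, 4))
        for i, (a, b, h) in enumerate(self.merges):
            sizes[n + i] = sizes[a] + sizes[b]
            Z[i] = (a, b, h, sizes[n + i])
        return Z


def pairwise_distances(events: EventMatrix | np.ndarray) -> np.ndarray:
    """Condensed Euclidean distances over event rows (n*(n-1)/2 values)."""
    X = events.events if isinstance(events, EventMatrix) else np.asarray(events, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("events must be 2-D")
    if X.shape[0] < 2:
        raise ValueError("need >= 2 events for pairwise distances")
    return pdist(X, metric="euclidean")


def build_tree(events: EventMatrix | np.ndarray) -> DendroTree:
    """Ward linkage on Euclidean distances; deterministic for a given input.

    Never materialises more than the condensed distance set (the linkage
    itself works in-place on that set).
    """
    D = pairwise_distances(events)
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite pairwise distances")
    Z = linkage(D, method="ward")
    return DendroTree.from_linkage(Z)


def to_newick(tree: DendroTree, labels: list[str] | None = None) -> str:
    """Newick string with merge heights encoded as branch lengths."""
    n = tree.n_leaves
    if labels is None:
        labels = [str(i) for i in range(n)]
    if len(labels) != n:
        raise ValueError(f"need {n} labels, got {len(labels)}")

    # iterative post-order to survive deep (unbalanced) trees
    parts: dict[int, str] = {}
    stack: list[tuple[int, bool]] = [(tree.root, False)]
    while stack:
        node, expanded = stack.pop()
        if node < n:
            parts[node] = str(labels[node])
            continue
        a, b = tree.children(node)
        if not expanded:
            stack.append((node, True))
            stack.append((a, False))
            stack.append((b, False))
        else:
            h = tree.height(node)
            la = max(h - tree.height(a), 0.0)
            lb = max(h - tree.height(b), 0.0)
            parts[node] = f"({parts[a]}:{la:g},{parts[b]}:{lb:g})"
            del parts[a], parts[b]
    return parts[tree.root] + ";"


def linkage_table(tree: DendroTree) -> list[dict[str, float]]:
    """Merge list as flat records (left, right, height, size) for CSV export."""
    Z = tree.to_linkage()
    return [
        {"left": int(a), "right": int(b), "height": float(h), "size": int(s)}
        for a, b, h, s in Z
    ]
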
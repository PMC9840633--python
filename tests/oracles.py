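"""Independent brute-force oracles, deliberately not sharing code paths
with the package implementations they check."""

from __future__ import annotations

import numpy as np

from dhsig.tree import DendroTree


def naive_ward(points: np.ndarray) -> list[tuple[int, int, float]]:
    """O(n^3) Ward agglomeration via the Lance-Williams update.

    Ties broken on the lexicographically smallest (small id, large id) pair.
    Returns scipy-style merges (child ids, distance-scale height).
    """
    points = np.asarray(points, dtype=np.float64)
    n = len(points)
    # squared-distance bookkeeping; report sqrt at merge time
    d2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            d2[(i, j)] = float(np.sum((points[i] - points[j]) ** 2))
    active = {i: 1 for i in range(n)}  # id -> cluster size
    merges = []
    next_id = n
    while len(active) > 1:
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if i >= j:
                    continue
                cand = (d2[(i, j)], i, j)
                if best is None or cand < best:
                    best = cand
        dist2, a, b = best
        sa, sb = active.pop(a), active.pop(b)
        merges.append((a, b, float(np.sqrt(dist2))))
        for k in sorted(active):
            sk = active[k]
            dak = d2[(min(a, k), max(a, k))]
            dbk = d2[(min(b, k), max(b, k))]
            new = ((sa + sk) * dak + (sb + sk) * dbk - sk * dist2) / (sa + sb + sk)
            d2[(k, next_id)] = new
        active[next_id] = sa + sb
        next_id += 1
    return merges


def merge_partitions(merges: list[tuple[int, int, float]], n: int) -> set[frozenset[int]]:
    """All internal-node leaf sets of a merge sequence (topology fingerprint)."""
    sets = [frozenset([i]) for i in range(n)]
    for a, b, _ in merges:
        sets.append(sets[a] | sets[b])
    return set(sets[n:])


def brute_force_codes(tree: DendroTree) -> dict[int, tuple[tuple[int, ...], int]]:
    """Recursive root-to-leaf walk: digit string and value per leaf.

    Same frozen conventions (root digit = 2^0 place, min-leaf subtree = 0)
    but a completely separate recursive traversal and value computation.
    """
    import sys

    n = tree.n_leaves
    sys.setrecursionlimit(max(10000, 4 * n))

    def leaves_under(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = tree.children(node)
        return leaves_under(a) + leaves_under(b)

    out: dict[int, tuple[tuple[int, ...], int]] = {}

    def walk(node: int, digits: list[int]) -> None:
        if node < n:
            value = sum(d * 2**j for j, d in enumerate(digits))
            out[node] = (tuple(digits), value)
            return
        a, b = tree.children(node)
        if min(leaves_under(a)) > min(leaves_under(b)):
            a, b = b, a
        walk(a, digits + [0])
        walk(b, digits + [1])

    walk(tree.root, [])
    return out


def dissection_count(tree: DendroTree, exponent: int) -> int:
    """Number of sub-dendrograms dissected by a threshold at depth `exponent`.

    Counts nodes at depth exactly `exponent` plus leaves shallower than
    that: each is the root of one disconnected sub-dendrogram below the
    threshold line, and each contributes exactly one sub-threshold branch.
    """
    if exponent <= 0:
        return 1  # only the all-zeros branch (the threshold sits at/below the root)
    count = 0
    stack = [(tree.root, 0)]
    n = tree.n_leaves
    while stack:
        node, depth = stack.pop()
        if depth == exponent:
            count += 1
            continue
        if node < n:  # leaf shallower than the threshold depth
            count += 1
            continue
        a, b = tree.children(node)
        stack.append((a, depth + 1))
        stack.append((b, depth + 1))
    return count


def pair_count_auc(scores, labels) -> float:
    """AUC by exhaustive positive/negative pair comparison (ties = 1/2)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def random_binary_tree(rng: np.random.Generator, n_leaves: int) -> DendroTree:
    """Uniform-ish random merge topology with increasing heights."""
    nodes = list(range(n_leaves))
    merges = []
    next_id = n_leaves
    h = 0.0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        h += float(rng.uniform(0.1, 1.0))
        merges.append((a, b, h))
        nodes.append(next_id)
        next_id += 1
    return DendroTree(n_leaves=n_leaves, merges=merges)
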
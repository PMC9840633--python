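"""2-adic encoding of binary dendrograms.

Every leaf is labelled by the binary digits of its root-to-leaf path; digit
``a_0`` is the choice at the ROOT split and digit ``a_k`` the choice at the
leaf's final split, giving the branch value

    V_i = sum_j a_j * 2**j,   a_j in {0, 1}.

Orientation convention (frozen): the root digit occupies the lowest-order
place, so |V_a - V_b| is 2-adically small exactly when the common
root-branch of the two leaves is long. At each internal node the child
subtree containing the smallest leaf id takes digit 0, the other digit 1.
Values are arbitrary-precision integers: deep trees overflow 64-bit words.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from dhsig.tree import DendroTree

__all__ = [
    "BranchCode",
    "CodedTree",
    "assign_codes",
    "two_adic_distance",
    "ball_of",
    "count_below_power",
]

NEG_INF = float("-inf")


@dataclass(frozen=True)
class BranchCode:
    """Digit path and 2-adic value of one leaf (branch) of a coded tree."""

    leaf_id: int
    digits: tuple[int, ...]  # a_0 (root split) .. a_k (final split)
    value: int  # sum a_j * 2**j, exact
    tree_id: int  # identity of the owning CodedTree

    @property
    def depth(self) -> int:
        return len(self.digits)

    @property
    def ball(self) -> float:
        return ball_of(self.value) if self.value >= 1 else NEG_INF


@dataclass
class CodedTree:
    """A dendrogram plus one BranchCode per leaf and its maximal 2-adic ball."""

    tree: DendroTree
    codes: list[BranchCode]
    max_ball: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.codes) != self.tree.n_leaves:
            raise ValueError("one code per leaf required")
        max_v = max(c.value for c in self.codes)
        if max_v < 1:
            raise ValueError("degenerate coding: no leaf with value >= 1")
        self.max_ball = max_v.bit_length() - 1  # == floor(log2(max V_i))

    @property
    def n_leaves(self) -> int:
        return self.tree.n_leaves

    def values(self) -> list[int]:
        return [c.value for c in self.codes]


def assign_codes(tree: DendroTree) -> CodedTree:
    """Label every leaf with its root-to-leaf digit string and value V_i."""
    n = tree.n_leaves
    min_leaf = tree.min_leaf_ids()
    codes: list[BranchCode | None] = [None] * n
    tid = id(tree)

    if n == 1:
        raise ValueError("cannot code a single-leaf tree")

    # DFS from the root carrying (node, accumulated value, depth, digit path)
    stack: list[tuple[int, int, int, tuple[int, ...]]] = [(tree.root, 0, 0, ())]
    while stack:
        node, acc, depth, path = stack.pop()
        if node < n:
            codes[node] = BranchCode(leaf_id=node, digits=path, value=acc, tree_id=tid)
            continue
        a, b = tree.children(node)
        zero, one = (a, b) if min_leaf[a] < min_leaf[b] else (b, a)
        stack.append((zero, acc, depth + 1, path + (0,)))
        stack.append((one, acc + (1 << depth), depth + 1, path + (1,)))
    return CodedTree(tree=tree, codes=codes)  # type: ignore[arg-type]


def two_adic_distance(code_a: BranchCode, code_b: BranchCode) -> Fraction:
    """2^(-L) where L is the common-prefix length of the digit paths; 0 iff same leaf."""
    if code_a.tree_id != code_b.tree_id:
        raise ValueError("codes come from different trees")
    if code_a.leaf_id == code_b.leaf_id:
        return Fraction(0)
    L = 0
    for da, db in zip(code_a.digits, code_b.digits):
        if da != db:
            break
        L += 1
    return Fraction(1, 1 << L)


def ball_of(value: int) -> float:
    """floor(log2 V) for V >= 1; the V=0 branch has no finite ball (-inf).

    The -inf sentinel sits below every threshold exponent, so the all-zeros
    branch always counts as sub-threshold.
    """
    if value < 0:
        raise ValueError(f"branch value must be nonnegative, got {value}")
    if value == 0:
        return NEG_INF
    return float(value.bit_length() - 1)


def count_below_power(values: list[int], exponent: int) -> int:
    """Exact count of values v with v < 2**exponent (exponent may be negative).

    For v >= 1: v < 2**e  <=>  bit_length(v) <= e. v = 0 is below any power.
    Done in integer arithmetic so arbitrary-size V_i compare exactly.
    """
    if exponent <= 0:
        return sum(1 for v in values if v == 0)
    return sum(1 for v in values if v == 0 or v.bit_length() <= exponent)
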
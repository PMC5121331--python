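"""Family-tree addition algebra for division-destiny (DD) vectors.

A clonal family tree is a rooted binary tree: internal vertices are cells
that divided, leaves are cells that returned to quiescence, and a leaf's
generation is its depth.  All DD-relevant information in a tree is carried
by its *DD vector* ``x`` with ``x_i`` = number of quiescent cells in
generation ``i`` — equivalently the coefficients of the leaf generating
function ``X(s) = sum_i x_i s^i``.

Adding the expansion effect of a second stimulus corresponds to
concatenating a second tree into the first.  The central theorem of this
module: however the second tree is interlaced into the first (at any
final-cell partition of vertices), the DD vector of the concatenated tree
is the convolution ``x * y`` of the two input DD vectors, i.e. the product
of the generating functions.  Consequently maxDD and the cohort-normalized
mean DD (mDD) are additive under concatenation.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ExplicitTree",
    "cohort_mass",
    "concatenate_explicit",
    "convolve",
    "dd_vector",
    "maxdd",
    "mdd",
    "random_partition_plan",
    "random_tree",
]


# ---------------------------------------------------------------------------
# DD vectors
# ---------------------------------------------------------------------------

def _as_ddvector(x: Sequence[int]) -> np.ndarray:
    arr = np.asarray(x, dtype=np.int64)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("DD vector must be a non-empty 1-d integer sequence")
    if np.any(arr < 0):
        raise ValueError("DD vector entries must be non-negative")
    if not np.any(arr > 0):
        raise ValueError("DD vector must have at least one positive entry")
    return arr


def convolve(x: Sequence[int], y: Sequence[int]) -> np.ndarray:
    """Convolution ``v_i = sum_j x_j y_{i-j}`` of two DD vectors.

    This is the DD vector of any concatenation of trees with DD vectors
    ``x`` and ``y``; cohort mass multiplies under it.
    """
    return np.convolve(_as_ddvector(x), _as_ddvector(y))


def cohort_mass(x: Sequence[int]) -> Fraction:
    """Exact cohort mass ``sum_i x_i 2^{-i}`` (1 for any full binary tree)."""
    arr = _as_ddvector(x)
    return sum(
        (Fraction(int(v), 2**i) for i, v in enumerate(arr)), Fraction(0)
    )


def maxdd(x: Sequence[int]) -> int:
    """Largest generation with a quiescent cell; additive under convolve."""
    arr = _as_ddvector(x)
    return int(np.nonzero(arr)[0][-1])


def mdd(x: Sequence[int]) -> float:
    """Cohort-normalized mean DD ``sum_i i (x_i 2^{-i}) / sum_j x_j 2^{-j}``.

    Computed in exact integer arithmetic before the final division, so
    additivity under :func:`convolve` holds to float rounding.
    """
    arr = _as_ddvector(x)
    # common denominator 2^(L-1): weight x_i 2^{-i} -> x_i 2^(L-1-i)
    L = arr.size
    weights = [int(v) << (L - 1 - i) for i, v in enumerate(arr)]
    total = sum(weights)
    num = sum(i * w for i, w in enumerate(weights))
    return num / total


# ---------------------------------------------------------------------------
# Explicit trees
# ---------------------------------------------------------------------------

class ExplicitTree:
    """A rooted tree of binary cell divisions.

    Leaves are quiescent (DD) cells; every internal vertex has exactly two
    children.  A leaf's generation equals its depth.
    """

    __slots__ = ("children",)

    def __init__(self, children: Iterable["ExplicitTree"] = ()):
        children = tuple(children)
        if len(children) not in (0, 2):
            raise ValueError("each dividing cell has exactly 2 daughters")
        self.children = children

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(c.depth() for c in self.children)

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return sum(c.n_leaves() for c in self.children)

    def subtree(self, path: tuple[int, ...]) -> "ExplicitTree":
        node = self
        for step in path:
            node = node.children[step]
        return node

    def __eq__(self, other):
        if not isinstance(other, ExplicitTree):
            return NotImplemented
        return self.children == other.children

    def __hash__(self):
        return hash(self.children)

    def __repr__(self):
        if self.is_leaf:
            return "Leaf"
        return f"Tree({self.children[0]!r}, {self.children[1]!r})"


LEAF = ExplicitTree()


def dd_vector(tree: ExplicitTree) -> np.ndarray:
    """DD vector of an explicit tree: quiescent-cell counts per generation."""
    counts: dict[int, int] = {}

    stack = [(tree, 0)]
    while stack:
        node, gen = stack.pop()
        if node.is_leaf:
            counts[gen] = counts.get(gen, 0) + 1
        else:
            stack.extend((c, gen + 1) for c in node.children)
    out = np.zeros(max(counts) + 1, dtype=np.int64)
    for g, n in counts.items():
        out[g] = n
    return out


def random_tree(
    rng: np.random.Generator, max_depth: int = 5, p_divide: float = 0.6
) -> ExplicitTree:
    """Draw a random binary tree: each cell divides w.p. ``p_divide`` until
    ``max_depth``."""
    if max_depth == 0 or rng.random() >= p_divide:
        return LEAF
    return ExplicitTree(
        (random_tree(rng, max_depth - 1, p_divide),
         random_tree(rng, max_depth - 1, p_divide))
    )


# ---------------------------------------------------------------------------
# Interlacing plans and concatenation
# ---------------------------------------------------------------------------

def _all_leaf_paths(tree: ExplicitTree) -> list[tuple[int, ...]]:
    if tree.is_leaf:
        return [()]
    out = []
    for i, child in enumerate(tree.children):
        out.extend((i, *p) for p in _all_leaf_paths(child))
    return out


def _validate_plan(tree: ExplicitTree, plan: set[tuple[int, ...]]) -> None:
    """A valid plan is a set of vertices whose descendant leaves partition
    all leaves: every root-to-leaf path meets exactly one plan vertex."""
    for leaf_path in _all_leaf_paths(tree):
        prefixes = [leaf_path[:k] for k in range(len(leaf_path) + 1)]
        hits = sum(p in plan for p in prefixes)
        if hits != 1:
            raise ValueError(
                f"insertion plan is not a final-cell partition: leaf {leaf_path} "
                f"covered {hits} times"
            )


def random_partition_plan(
    tree: ExplicitTree, rng: np.random.Generator, p_stop: float = 0.4
) -> set[tuple[int, ...]]:
    """Random final-cell partition: descend from the root, cutting at each
    vertex w.p. ``p_stop`` (leaves are always cut)."""
    plan: set[tuple[int, ...]] = set()

    def descend(node: ExplicitTree, path: tuple[int, ...]) -> None:
        if node.is_leaf or rng.random() < p_stop:
            plan.add(path)
            return
        for i, child in enumerate(node.children):
            descend(child, (*path, i))

    descend(tree, ())
    return plan


def _graft_at_leaves(tree: ExplicitTree, sub: ExplicitTree) -> ExplicitTree:
    """Replace every leaf of ``tree`` by (a copy of) ``sub``."""
    if tree.is_leaf:
        return sub
    return ExplicitTree(_graft_at_leaves(c, sub) for c in tree.children)


def concatenate_explicit(
    first: ExplicitTree,
    second: ExplicitTree,
    plan: set[tuple[int, ...]] | frozenset[tuple[int, ...]] | None = None,
) -> ExplicitTree:
    """Concatenate ``second`` into ``first`` at an insertion plan.

    ``plan`` is a final-cell partition of vertices of ``first`` (paths from
    the root, as tuples of 0/1).  At each plan vertex the second tree is
    inserted and the remaining subtree of ``first`` rooted there is
    re-appended at each of its quiescent cells.  ``plan=None`` appends
    ``second`` at every leaf of ``first``.

    Whatever the plan, the DD vector of the result equals
    ``convolve(dd_vector(first), dd_vector(second))``.
    """
    if plan is None:
        plan = set(_all_leaf_paths(first))
    else:
        plan = set(plan)
        _validate_plan(first, plan)

    def build(node: ExplicitTree, path: tuple[int, ...]) -> ExplicitTree:
        if path in plan:
            # insert second here; its quiescent cells continue with the
            # remainder of the first tree rooted at this vertex
            return _graft_at_leaves(second, node)
        return ExplicitTree(
            build(c, (*path, i)) for i, c in enumerate(node.children)
        )

    return build(first, ())
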
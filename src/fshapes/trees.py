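"""Ranked tree shapes.

A ranked tree shape is a rooted full binary tree with a total order on
(some of) its nodes, compatible with the root-to-leaf direction.  Two
flavours are supported:

* **fully heterochronous** -- all ``2n - 1`` nodes, leaves included, carry
  distinct ranks ``0 .. 2n - 2``; the root has rank 0 and the oldest rank
  ``2n - 2`` is necessarily a leaf.  This is the discretisation of a rooted
  phylogram, where leaf positions are part of the inferential output.
* **isochronous** -- only the ``n - 1`` internal nodes are ranked
  (``0 .. n - 2``); every leaf carries the shared terminal rank ``n - 1``.
  This is the discretisation of a time tree.

Ranks double as (unit-spaced) event times: the event of rank ``i`` happens
at epoch ``i``, so an edge from a parent of rank ``p`` to a child of rank
``c`` survives ``c - p`` inter-event intervals.  That convention gives the
integer branch-length statistics computed by :func:`branch_lengths`.

Isochronous leaves are bookkept with synthetic negative ids (their rank is
implicitly ``n - 1``); the ids carry no information and are ignored by
equality, which compares canonical F-matrix encodings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "Mode",
    "RankedTreeShape",
    "make_tree",
    "full_cherry_tree",
    "strip_cherries",
    "count_cherries",
    "branch_lengths",
]


class Mode(str, Enum):
    """Flavour of ranked tree shape (and of its matrix encodings)."""

    ISOCHRONOUS = "isochronous"
    HETEROCHRONOUS = "fully_heterochronous"


_MODE_ALIASES = {
    "iso": Mode.ISOCHRONOUS,
    "isochronous": Mode.ISOCHRONOUS,
    "het": Mode.HETEROCHRONOUS,
    "heterochronous": Mode.HETEROCHRONOUS,
    "fully_heterochronous": Mode.HETEROCHRONOUS,
}


def coerce_mode(mode: "Mode | str") -> Mode:
    if isinstance(mode, Mode):
        return mode
    try:
        return _MODE_ALIASES[str(mode).lower()]
    except KeyError:
        raise ValueError(f"unknown mode {mode!r}") from None


@dataclass(frozen=True)
class RankedTreeShape:
    """A validated ranked tree shape.

    ``parent_of`` maps every non-root node to its parent's rank.  Nodes are
    integers: ranks for ranked nodes, negative synthetic ids for isochronous
    leaves.  Construct through :func:`make_tree`, which enforces all
    invariants.
    """

    n_leaves: int
    mode: Mode
    parent_of: dict[int, int] = field(repr=False)

    # -- structure ---------------------------------------------------------

    def children_of(self) -> dict[int, list[int]]:
        kids: dict[int, list[int]] = {}
        for child, parent in self.parent_of.items():
            kids.setdefault(parent, []).append(child)
        for v in kids.values():
            v.sort()
        return kids

    def nodes(self) -> list[int]:
        return sorted(set(self.parent_of) | set(self.parent_of.values()))

    def leaves(self) -> list[int]:
        parents = set(self.parent_of.values())
        return [v for v in self.nodes() if v not in parents]

    def internal_nodes(self) -> list[int]:
        return sorted(set(self.parent_of.values()))

    def effective_rank(self, node: int) -> int:
        """Rank used by the matrix encodings; iso leaves count as ``n - 1``."""
        if node < 0:
            return self.n_leaves - 1
        return node

    def edges(self) -> Iterator[tuple[int, int]]:
        """Yield ``(parent_rank, child_node)`` pairs."""
        for child, parent in sorted(self.parent_of.items()):
            yield parent, child

    # -- canonical form ----------------------------------------------------

    def f_entries(self) -> np.ndarray:
        """The F-matrix entries: ``F[i, j]`` counts edges from a node of
        rank <= j to a node of rank > i (iso leaves ranking as ``n - 1``)."""
        size = (self.n_leaves - 1 if self.mode is Mode.ISOCHRONOUS
                else 2 * self.n_leaves - 2)
        F = np.zeros((size, size), dtype=np.int64)
        for parent, child in self.edges():
            rw = self.effective_rank(child)
            F[:rw, parent:] += 1
        return np.tril(F)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RankedTreeShape):
            return NotImplemented
        return (self.n_leaves == other.n_leaves
                and self.mode is other.mode
                and np.array_equal(self.f_entries(), other.f_entries()))

    def __hash__(self) -> int:
        return hash((self.n_leaves, self.mode, self.f_entries().tobytes()))


def make_tree(parent_pairs: Iterable[tuple[int, int]], n_leaves: int,
              mode: Mode | str) -> RankedTreeShape:
    """Build and validate a ranked tree shape from ``(child, parent)`` pairs.

    Heterochronous mode expects one pair per non-root rank ``1 .. 2n - 2``.
    Isochronous mode expects pairs for internal ranks ``1 .. n - 2`` plus
    one pair per leaf; a leaf child may be written either as a negative
    synthetic id or as the shared leaf rank ``n - 1`` (repeats allowed, each
    occurrence becoming a fresh leaf).
    """
    mode = coerce_mode(mode)
    if n_leaves < 2:
        raise ValueError("a ranked tree shape needs at least 2 leaves")
    n = n_leaves

    parent_of: dict[int, int] = {}
    next_leaf_id = -1
    for child, parent in parent_pairs:
        child, parent = int(child), int(parent)
        if mode is Mode.ISOCHRONOUS and (child < 0 or child == n - 1):
            node = next_leaf_id if child == n - 1 else child
            if child == n - 1:
                next_leaf_id -= 1
            if node in parent_of:
                raise ValueError(f"duplicate leaf id {node}")
            if not 0 <= parent <= n - 2:
                raise ValueError(f"leaf parent {parent} is not an internal rank")
            parent_of[node] = parent
            continue
        if child in parent_of:
            raise ValueError(f"duplicate child rank {child}")
        if child <= parent:
            raise ValueError(
                f"rank order violated: child {child} <= parent {parent}")
        parent_of[child] = parent

    tree = RankedTreeShape(n_leaves=n, mode=mode, parent_of=parent_of)
    _validate(tree)
    return tree


def _validate(tree: RankedTreeShape) -> None:
    n = tree.n_leaves
    nodes = set(tree.parent_of) | set(tree.parent_of.values())
    if 0 not in nodes or 0 in tree.parent_of:
        raise ValueError("missing root of rank 0")

    kids = tree.children_of()
    for parent, ch in kids.items():
        if len(ch) != 2:
            raise ValueError(f"node {parent} has out-degree {len(ch)}, not 2")
        for c in ch:
            if tree.effective_rank(c) <= parent:
                raise ValueError(f"rank order violated on edge ({parent}, {c})")

    leaves = [v for v in nodes if v not in kids]
    if len(leaves) != n:
        raise ValueError(f"expected {n} leaves, found {len(leaves)}")

    if tree.mode is Mode.HETEROCHRONOUS:
        if nodes != set(range(2 * n - 1)):
            raise ValueError("heterochronous ranks must be exactly 0..2n-2")
        if 2 * n - 2 not in leaves:
            raise ValueError("the oldest rank 2n-2 must be a leaf")
    else:
        internals = set(kids)
        if internals != set(range(n - 1)):
            raise ValueError("isochronous internal ranks must be exactly 0..n-2")
        if any(v >= 0 for v in leaves):
            raise ValueError("isochronous leaves must carry synthetic ids")

    # connectivity: every node must reach the root
    for v in nodes:
        seen = set()
        while v != 0:
            if v in seen:
                raise ValueError("cycle in parent map")
            seen.add(v)
            v = tree.parent_of[v]


def full_cherry_tree(tree: RankedTreeShape) -> RankedTreeShape:
    """Map an n-leaf fully heterochronous tree to the isochronous 2n-leaf
    tree obtained by hanging a cherry from each of its leaves.

    The map is a bijection onto full-cherry trees (every leaf in a cherry);
    :func:`strip_cherries` inverts it.
    """
    if tree.mode is not Mode.HETEROCHRONOUS:
        raise ValueError("full_cherry_tree expects a fully heterochronous tree")
    n = tree.n_leaves
    parent_of = dict(tree.parent_of)
    leaf_id = -1
    for leaf in tree.leaves():
        for _ in range(2):
            parent_of[leaf_id] = leaf
            leaf_id -= 1
    out = RankedTreeShape(n_leaves=2 * n, mode=Mode.ISOCHRONOUS,
                          parent_of=parent_of)
    _validate(out)
    return out


def strip_cherries(tree: RankedTreeShape) -> RankedTreeShape:
    """Inverse of :func:`full_cherry_tree`; rejects trees that are not
    full-cherry (some leaf not in a cherry)."""
    if tree.mode is not Mode.ISOCHRONOUS or tree.n_leaves % 2:
        raise ValueError("strip_cherries expects an isochronous full-cherry tree")
    kids = tree.children_of()
    parent_of = dict(tree.parent_of)
    for parent, ch in kids.items():
        if any(c < 0 for c in ch):
            if not all(c < 0 for c in ch):
                raise ValueError(f"leaf of node {parent} is not in a cherry")
            for c in ch:
                del parent_of[c]
    out = RankedTreeShape(n_leaves=tree.n_leaves // 2,
                          mode=Mode.HETEROCHRONOUS, parent_of=parent_of)
    _validate(out)
    return out


def count_cherries(tree: RankedTreeShape) -> int:
    """Number of internal nodes whose two children are both leaves."""
    leaves = set(tree.leaves())
    return sum(1 for ch in tree.children_of().values()
               if all(c in leaves for c in ch))


def branch_lengths(tree: RankedTreeShape) -> tuple[int, int]:
    """``(total_length, internal_length)`` of a fully heterochronous tree
    under the unit-epoch convention.

    Each edge contributes ``rank(child) - rank(parent)`` epochs to the
    total; internal length keeps only edges whose child is internal.  The
    total equals the sum of the F-matrix diagonal.
    """
    if tree.mode is not Mode.HETEROCHRONOUS:
        raise ValueError("branch_lengths expects a fully heterochronous tree")
    internal = set(tree.internal_nodes())
    total = 0
    internal_len = 0
    for parent, child in tree.edges():
        length = child - parent
        total += length
        if child in internal:
            internal_len += length
    return total, internal_len
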
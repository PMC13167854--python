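"""Single-pass autoregressive construction and exact counting.

An F-matrix can be filled one entry at a time in lexicographic
(row-then-column) order without ever backtracking: at each position the
admissible values are determined by at most four previously filled entries
(left, above, above-left and the previous diagonal entry).  Every position
admits one or two values, so the whole space of ranked tree shapes of a
given size unfolds as a binary decision tree whose leaves are exactly the
valid F-matrices.

This module provides that machinery (:class:`FSequence`,
:func:`admissible_values`, :func:`enumerate_f_matrices`), the Dyck-path
view of the heterochronous diagonal (:func:`diagonal_feasible`,
:func:`count_diagonals`, :func:`enumerate_with_diagonal`) and exact counts
of ranked tree shapes by three independent routes (:func:`count_shapes`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator, Sequence

import numpy as np

from .matrices import FMatrix
from .trees import Mode, coerce_mode

__all__ = [
    "Bounds",
    "FSequence",
    "bounds",
    "admissible_values",
    "enumerate_f_matrices",
    "enumerate_with_diagonal",
    "count_shapes",
    "diagonal_feasible",
    "count_diagonals",
    "count_choice_positions",
    "choice_positions",
    "catalan",
]


# ---------------------------------------------------------------------------
# partial matrices and extension rules


@dataclass(frozen=True)
class Bounds:
    """The local lower/upper bounds L_F(i, j) and U_F(i, j)."""

    lower: int
    upper: int


def _get(rows: Sequence[Sequence[int]], i: int, j: int) -> int:
    """Entry accessor with the out-of-bound-reads-as-0 convention."""
    if i < 0 or j < 0:
        return 0
    return rows[i][j]


def bounds(rows: Sequence[Sequence[int]], i: int, j: int) -> Bounds:
    """L/U bounds at position ``(i, j)`` given all earlier entries:

    ``L = max(F[i,j-1], F[i-1,j] - 1, F[i,j-1] + F[i-1,j] - F[i-1,j-1] - 1)``
    ``U = min(F[i-1,j],               F[i,j-1] + F[i-1,j] - F[i-1,j-1])``
    """
    left = _get(rows, i, j - 1)
    up = _get(rows, i - 1, j)
    upleft = _get(rows, i - 1, j - 1)
    lower = max(left, up - 1, left + up - upleft - 1)
    upper = min(up, left + up - upleft)
    return Bounds(lower, upper)


@dataclass
class FSequence:
    """A partially filled F-matrix in lexicographic fill order.

    ``rows`` holds complete rows ``0 .. N-1`` plus the first ``M + 1``
    entries of row ``N``.  The invariants of a valid F-sequence (diagonal
    feasibility, the L/U band and the collision rule forcing
    ``f[i, j] = f[i-1, i-1] - 1`` whenever ``f[i-1, j] = f[i-1, i-1]``)
    guarantee that any such prefix extends to a complete matrix.
    """

    n_leaves: int
    mode: Mode
    rows: list[list[int]] = field(default_factory=list)

    @classmethod
    def start(cls, n_leaves: int, mode: Mode | str) -> "FSequence":
        """The unique length-1 prefix (F[0,0] = 2 in both flavours)."""
        if n_leaves < 2:
            raise ValueError("n_leaves must be >= 2")
        return cls(n_leaves=n_leaves, mode=coerce_mode(mode), rows=[[2]])

    @property
    def size(self) -> int:
        return (self.n_leaves - 1 if self.mode is Mode.ISOCHRONOUS
                else 2 * self.n_leaves - 2)

    @property
    def cursor(self) -> tuple[int, int]:
        """(N, M): the last filled position."""
        return len(self.rows) - 1, len(self.rows[-1]) - 1

    @property
    def complete(self) -> bool:
        N, M = self.cursor
        return N == self.size - 1 and M == N

    def next_position(self) -> tuple[int, int]:
        N, M = self.cursor
        return (N, M + 1) if M < N else (N + 1, 0)

    def extended(self, value: int) -> "FSequence":
        N, M = self.cursor
        if M < N:
            rows = self.rows[:-1] + [self.rows[-1] + [value]]
        else:
            rows = self.rows + [[value]]
        return FSequence(self.n_leaves, self.mode, rows)

    def to_matrix(self, validate: bool = False) -> FMatrix:
        if not self.complete:
            raise ValueError("F-sequence is not complete")
        size = self.size
        A = np.zeros((size, size), dtype=np.int64)
        for i, row in enumerate(self.rows):
            A[i, : i + 1] = row
        return FMatrix.from_entries(A, self.mode, validate=validate)


def _admissible(rows: list[list[int]], i: int, j: int, n: int,
                mode: Mode) -> list[int]:
    """Legal values for position ``(i, j)``, given rows filled up to it.

    Returns values in increasing order; the list has length 1 or 2.
    """
    if mode is Mode.ISOCHRONOUS:
        if j == i:
            return [i + 2]
        if j == i - 1:
            return [i]
        b = bounds(rows, i, j)
        return [b.lower] if b.lower == b.upper else [b.lower, b.upper]

    # fully heterochronous
    prev_diag = rows[i - 1][i - 1] if i else None
    if i == 0:
        return [2]
    if j == i:  # diagonal: +/- 1 within the feasibility band
        vals = []
        if prev_diag > 1:
            vals.append(prev_diag - 1)
        if prev_diag < 2 * n - i - 1:
            vals.append(prev_diag + 1)
        return vals
    if j == i - 1:  # subdiagonal: forced
        return [prev_diag - 1]
    # off-diagonal: forced on a collision with the previous diagonal value
    if rows[i - 1][j] == prev_diag:
        return [prev_diag - 1]
    b = bounds(rows, i, j)
    return [b.lower] if b.lower == b.upper else [b.lower, b.upper]


def admissible_values(seq: FSequence) -> list[int]:
    """Values that legally extend ``seq`` at its next lexicographic position.

    Always non-empty on a reachable state (the construction never needs to
    backtrack); raises on a complete sequence.
    """
    if seq.complete:
        raise ValueError("F-sequence is already complete")
    i, j = seq.next_position()
    return _admissible(seq.rows, i, j, seq.n_leaves, seq.mode)


# ---------------------------------------------------------------------------
# enumeration


def enumerate_f_matrices(n: int, mode: Mode | str, *,
                         diagonal: Sequence[int] | None = None,
                         cap: int | None = 10**7) -> Iterator[FMatrix]:
    """Lazily yield every F-matrix for ``n`` leaves, depth-first in
    lexicographic order of entry choices.

    ``diagonal`` pins the diagonal (heterochronous only).  ``cap`` guards
    against accidentally traversing a super-exponentially large space; pass
    ``None`` to lift it.
    """
    mode = coerce_mode(mode)
    if n < 2:
        raise ValueError("n must be >= 2")
    if diagonal is not None:
        if mode is not Mode.HETEROCHRONOUS:
            raise ValueError("pinned diagonals apply to heterochronous matrices")
        diagonal = [int(x) for x in diagonal]
        if len(diagonal) != 2 * n - 2 or not diagonal_feasible(diagonal, n):
            raise ValueError(f"infeasible diagonal {diagonal} for n={n}")
    if cap is not None and count_shapes(n, mode, "recursion") > cap:
        raise ValueError(
            f"enumeration at n={n} ({mode.value}) exceeds cap={cap}; "
            "pass cap=None to override")

    size = (n - 1) if mode is Mode.ISOCHRONOUS else (2 * n - 2)
    rows: list[list[int]] = [[2]]

    def fill(i: int, j: int) -> Iterator[FMatrix]:
        if i == size:
            A = np.zeros((size, size), dtype=np.int64)
            for r, row in enumerate(rows):
                A[r, : r + 1] = row
            yield FMatrix.from_entries(A, mode, validate=False)
            return
        values = _admissible(rows, i, j, n, mode)
        if diagonal is not None and i == j:
            values = [v for v in values if v == diagonal[i]]
        ni, nj = (i, j + 1) if j < i else (i + 1, 0)
        for v in values:
            if j == 0:
                rows.append([v])
            else:
                rows[i].append(v)
            yield from fill(ni, nj)
            if j == 0:
                rows.pop()
            else:
                rows[i].pop()

    if diagonal is not None and diagonal[0] != 2:
        return
    yield from fill(1, 0)


def enumerate_with_diagonal(diagonal: Sequence[int], n: int,
                            cap: int | None = 10**7) -> Iterator[FMatrix]:
    """All heterochronous F-matrices whose diagonal equals ``diagonal``."""
    return enumerate_f_matrices(n, Mode.HETEROCHRONOUS,
                                diagonal=diagonal, cap=cap)


# ---------------------------------------------------------------------------
# diagonals as Dyck paths


def diagonal_feasible(prefix: Sequence[int], n: int) -> bool:
    """Whether ``prefix`` extends to (or is) the diagonal of some
    heterochronous F-matrix for ``n`` leaves: starts at 2, steps by +/- 1,
    stays positive, and leaves room to come back down to 1
    (``f_i <= 2n - i - 2``).  A complete length-(2n-2) prefix must end at 1.
    """
    prefix = [int(x) for x in prefix]
    if not prefix or len(prefix) > 2 * n - 2:
        return False
    if prefix[0] != 2:
        return False
    for i, f in enumerate(prefix):
        if f <= 0 or f > 2 * n - i - 2:
            return False
        if i and abs(f - prefix[i - 1]) != 1:
            return False
    if len(prefix) == 2 * n - 2 and prefix[-1] != 1:
        return False
    return True


def catalan(m: int) -> int:
    return math.comb(2 * m, m) // (m + 1)


def count_diagonals(n: int) -> int:
    """Number of distinct complete diagonals: the Catalan number C_{n-1}."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return catalan(n - 1)


# ---------------------------------------------------------------------------
# exact counting


@lru_cache(maxsize=None)
def _count_het_recursion(n: int) -> int:
    # root-splitting recursion over full-cherry subtrees:
    # |T*_n| = 1/2 * sum_l C(2n-2, 2l-1) |T*_l| |T*_{n-l}|
    if n <= 2:
        return 1
    total = sum(math.comb(2 * n - 2, 2 * ell - 1)
                * _count_het_recursion(ell) * _count_het_recursion(n - ell)
                for ell in range(1, n))
    assert total % 2 == 0
    return total // 2


@lru_cache(maxsize=None)
def _zigzag(m: int) -> int:
    """Euler up/down (zigzag) number via the boustrophedon (Seidel) scheme."""
    row = [1]
    for k in range(1, m + 1):
        prev = row[::-1]
        row = [0]
        for x in prev:
            row.append(row[-1] + x)
    return row[-1]


def _count_closed_form(n: int, mode: Mode) -> int:
    import sympy

    if n == 1:
        return 1  # the Euler-polynomial form degenerates at n=1
    if mode is Mode.HETEROCHRONOUS:
        # 2^n (2^(2n) - 1) |B_(2n)| / n, exact rational arithmetic
        val = (sympy.Integer(2) ** n * (sympy.Integer(2) ** (2 * n) - 1)
               * abs(sympy.bernoulli(2 * n)) / n)
    else:
        # 2^(n-1) |E_(n-1)(1/2) - E_(n-1)(0)| with Euler polynomials
        x = sympy.Symbol("x")
        poly = sympy.euler(n - 1, x)
        val = (sympy.Integer(2) ** (n - 1)
               * abs(poly.subs(x, sympy.Rational(1, 2)) - poly.subs(x, 0)))
    val = sympy.Rational(val)
    assert val.q == 1
    return int(val.p)


def count_shapes(n: int, mode: Mode | str,
                 method: str = "recursion", *, max_enumeration_n: int = 8) -> int:
    """Exact number of ranked tree shapes with ``n`` leaves.

    ``method``:

    * ``recursion`` -- heterochronous: the root-splitting recursion over
      full-cherry trees; isochronous: the boustrophedon zigzag recurrence.
    * ``closed_form`` -- Bernoulli-number / Euler-polynomial closed forms,
      in exact rational arithmetic.
    * ``enumeration`` -- count the depth-first construction's leaves
      (guarded by ``max_enumeration_n``; the space grows super-exponentially).
    """
    mode = coerce_mode(mode)
    if n < 1:
        raise ValueError("n must be >= 1")
    if method == "recursion":
        if mode is Mode.HETEROCHRONOUS:
            return _count_het_recursion(n)
        return _zigzag(n - 1)
    if method == "closed_form":
        return _count_closed_form(n, mode)
    if method == "enumeration":
        if n == 1:
            return 1
        if n > max_enumeration_n:
            raise ValueError(
                f"enumeration guarded at n <= {max_enumeration_n}; "
                "raise max_enumeration_n to override")
        return sum(1 for _ in enumerate_f_matrices(n, mode, cap=None))
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# choice positions


def choice_positions(n: int, mode: Mode | str) -> list[tuple[int, int]]:
    """All positions that can branch (take two values) for some prefix.

    Heterochronous: the free diagonal positions ``(i, i)``, ``1 <= i <= 2n-5``,
    plus every position below the subdiagonal.  Isochronous: the positions
    below the subdiagonal only (diagonal and subdiagonal are fixed).
    Whether a given position actually branches depends on the prefix; these
    are the *potential* choice positions that a Bernoulli probability table
    must cover.
    """
    mode = coerce_mode(mode)
    if n < 3:
        raise ValueError("n must be >= 3")
    if mode is Mode.ISOCHRONOUS:
        return [(i, j) for i in range(2, n - 1) for j in range(i - 1)]
    pos = [(i, i) for i in range(1, 2 * n - 4)]
    pos += [(i, j) for i in range(2, 2 * n - 2) for j in range(i - 1)]
    return sorted(pos)


def count_choice_positions(n: int, mode: Mode | str) -> int:
    """Closed forms: ``(n-3)(n-2)/2`` isochronous, ``2n^2 - 5n + 1``
    heterochronous."""
    mode = coerce_mode(mode)
    if n < 3:
        raise ValueError("n must be >= 3")
    if mode is Mode.ISOCHRONOUS:
        return (n - 3) * (n - 2) // 2
    return 2 * n * n - 5 * n + 1
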
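"""F-, D- and E-matrix encodings of ranked tree shapes.

For a ranked tree shape with ranks doubling as event epochs:

* ``F[i, j]`` -- number of lineages present throughout the whole epoch
  window ``(u_{i+1}, u_j)``: edges from a node of rank <= j to a node of
  rank > i.
* ``D[i, j] = F[i, j] - F[i, j-1]`` -- descendants of the rank-j node still
  extant past epoch ``i``.
* ``E[i, j] = D[i, j] - D[i+1, j]`` -- offset adjacency: 1 exactly when the
  node of rank ``i + 1`` is a child of the node of rank ``j`` (in the
  isochronous case the last row instead counts leaf children, 0..2).

All three are lower-triangular and in bijection with each other and with
the tree.  ``validate_f`` decides membership of an arbitrary integer matrix
in the F-matrix class via the inequality characterisation: row and column
monotonicity, the diagonal/subdiagonal pattern (which differs between the
isochronous and fully heterochronous flavours) and the local four-entry
double inequality.

Matrix sizes: ``(n-1) x (n-1)`` isochronous, ``(2n-2) x (2n-2)`` fully
heterochronous.  Out-of-bound entries read as 0 everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .trees import Mode, RankedTreeShape, coerce_mode, make_tree

__all__ = [
    "FMatrix",
    "DMatrix",
    "EMatrix",
    "ValidationReport",
    "Violation",
    "f_from_tree",
    "tree_from_f",
    "d_from_f",
    "e_from_d",
    "f_from_d",
    "d_from_e",
    "e_from_f",
    "tree_from_e",
    "validate_f",
    "n_leaves_for_size",
]


def n_leaves_for_size(size: int, mode: Mode | str) -> int:
    """Invert the matrix-size convention; raises on an illegal size."""
    mode = coerce_mode(mode)
    if mode is Mode.ISOCHRONOUS:
        n = size + 1
    else:
        if size % 2:
            raise ValueError(f"heterochronous matrices have even size, got {size}")
        n = (size + 2) // 2
    if n < 2:
        raise ValueError(f"size {size} does not correspond to n >= 2")
    return n


def _as_square_int(entries) -> np.ndarray:
    A = np.asarray(entries)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrix must be square")
    if not np.issubdtype(A.dtype, np.integer):
        if not np.all(A == np.floor(A)):
            raise ValueError("matrix entries must be integers")
        A = A.astype(np.int64)
    return A.astype(np.int64)


@dataclass(frozen=True)
class _TriMatrix:
    """Shared container: a lower-triangular integer matrix plus mode."""

    n_leaves: int
    mode: Mode
    entries: np.ndarray

    def __post_init__(self):
        A = _as_square_int(self.entries)
        if np.any(np.triu(A, 1) != 0):
            raise ValueError("entries above the diagonal must be 0")
        expected = n_leaves_for_size(A.shape[0], self.mode)
        if expected != self.n_leaves:
            raise ValueError(
                f"size {A.shape[0]} inconsistent with n_leaves={self.n_leaves}")
        A.setflags(write=False)
        object.__setattr__(self, "entries", A)

    @property
    def size(self) -> int:
        return self.entries.shape[0]

    def __eq__(self, other) -> bool:
        if not isinstance(other, type(self)):
            return NotImplemented
        return (self.mode is other.mode
                and np.array_equal(self.entries, other.entries))

    def __hash__(self) -> int:
        return hash((type(self).__name__, self.mode, self.entries.tobytes()))


class FMatrix(_TriMatrix):
    def diagonal(self) -> list[int]:
        return [int(x) for x in np.diag(self.entries)]

    @classmethod
    def from_entries(cls, entries, mode: Mode | str,
                     validate: bool = True) -> "FMatrix":
        mode = coerce_mode(mode)
        A = _as_square_int(entries)
        n = n_leaves_for_size(A.shape[0], mode)
        if validate:
            report = validate_f(A, mode)
            if not report.valid:
                raise ValueError(f"not a valid F-matrix: {report.violations}")
        return cls(n_leaves=n, mode=mode, entries=A)


class DMatrix(_TriMatrix):
    pass


class EMatrix(_TriMatrix):
    pass


# ---------------------------------------------------------------------------
# tree <-> matrix and matrix <-> matrix conversions


def f_from_tree(tree: RankedTreeShape) -> FMatrix:
    """Encode a ranked tree shape as its F-matrix."""
    return FMatrix(n_leaves=tree.n_leaves, mode=tree.mode,
                   entries=tree.f_entries())


def d_from_f(F: FMatrix) -> DMatrix:
    A = F.entries
    D = A - np.pad(A, ((0, 0), (1, 0)))[:, :-1]
    D = np.tril(D)
    if np.any(D < 0) or np.any(D > 2):
        raise ValueError("input is not an F-matrix: derived D entries outside 0..2")
    return DMatrix(n_leaves=F.n_leaves, mode=F.mode, entries=D)


def e_from_d(D: DMatrix) -> EMatrix:
    A = D.entries
    E = A - np.pad(A, ((0, 1), (0, 0)))[1:, :]
    E = np.tril(E)
    if np.any(E < 0) or np.any(E > 2):
        raise ValueError("input is not a D-matrix: derived E entries outside 0..2")
    return EMatrix(n_leaves=D.n_leaves, mode=D.mode, entries=E)


def f_from_d(D: DMatrix) -> FMatrix:
    F = np.tril(np.cumsum(D.entries, axis=1))
    return FMatrix(n_leaves=D.n_leaves, mode=D.mode, entries=F)


def d_from_e(E: EMatrix) -> DMatrix:
    # D[i, j] = sum_{l >= i} E[l, j]: reverse cumulative sum down each column
    D = np.tril(np.cumsum(E.entries[::-1], axis=0)[::-1])
    return DMatrix(n_leaves=E.n_leaves, mode=E.mode, entries=D)


def e_from_f(F: FMatrix) -> EMatrix:
    return e_from_d(d_from_f(F))


def tree_from_e(E: EMatrix) -> RankedTreeShape:
    """Read the ranked tree shape off the offset adjacency matrix."""
    A = E.entries
    size = A.shape[0]
    n = E.n_leaves
    pairs: list[tuple[int, int]] = []
    if E.mode is Mode.HETEROCHRONOUS:
        for i in range(size):
            row = np.flatnonzero(A[i, : i + 1])
            if A[i].sum() != 1 or len(row) != 1 or A[i, row[0]] != 1:
                raise ValueError(f"E row {i} must contain a single 1")
            pairs.append((i + 1, int(row[0])))
        colsums = A.sum(axis=0)
        if not np.all(np.isin(colsums, (0, 2))):
            raise ValueError("E column sums must be 0 or 2")
    else:
        for i in range(size - 1):
            row = np.flatnonzero(A[i, : i + 1])
            if A[i].sum() != 1 or len(row) != 1 or A[i, row[0]] != 1:
                raise ValueError(f"E row {i} must contain a single 1")
            pairs.append((i + 1, int(row[0])))
        for j in range(size):
            for _ in range(int(A[size - 1, j])):
                pairs.append((n - 1, j))  # a leaf child of internal node j
    return make_tree(pairs, n_leaves=n, mode=E.mode)


def tree_from_f(F: FMatrix) -> RankedTreeShape:
    """Decode an F-matrix back to its ranked tree shape (via D and E)."""
    return tree_from_e(e_from_d(d_from_f(F)))


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Violation:
    condition: str  # row_monotone | col_monotone | diag | subdiag | local_3c
    position: tuple[int, int]
    message: str


@dataclass(frozen=True)
class ValidationReport:
    valid: bool
    violations: tuple[Violation, ...]

    def conditions(self) -> set[str]:
        return {v.condition for v in self.violations}


def validate_f(M, mode: Mode | str) -> ValidationReport:
    """Check every F-matrix condition on a lower-triangular integer matrix.

    All violations are reported, not just the first.  A size that matches
    neither flavour convention, a non-integer entry, a negative entry or a
    non-zero entry above the diagonal is an error (the input is outside the
    precondition), not a violation.
    """
    mode = coerce_mode(mode)
    A = _as_square_int(M)
    if np.any(A < 0):
        raise ValueError("entries must be non-negative")
    if np.any(np.triu(A, 1) != 0):
        raise ValueError("matrix must be lower triangular")
    n = n_leaves_for_size(A.shape[0], mode)
    size = A.shape[0]
    viol: list[Violation] = []

    def F(i: int, j: int) -> int:  # zero-padding convention
        if i < 0 or j < 0:
            return 0
        return int(A[i, j])

    # 1. rows monotone increasing
    for i in range(size):
        for j in range(1, i + 1):
            if F(i, j - 1) > F(i, j):
                viol.append(Violation("row_monotone", (i, j),
                                      f"F[{i},{j-1}]={F(i, j-1)} > F[{i},{j}]={F(i, j)}"))
    # 2. columns monotone decreasing with unit step
    for i in range(1, size):
        for j in range(i):
            if not F(i - 1, j) - 1 <= F(i, j) <= F(i - 1, j):
                viol.append(Violation("col_monotone", (i, j),
                                      f"F[{i},{j}]={F(i, j)} outside "
                                      f"[F[{i-1},{j}]-1, F[{i-1},{j}]]"))
    # 3a. diagonal
    if mode is Mode.ISOCHRONOUS:
        for i in range(size):
            if F(i, i) != i + 2:
                viol.append(Violation("diag", (i, i),
                                      f"F[{i},{i}]={F(i, i)} != {i + 2}"))
    else:
        if F(0, 0) != 2:
            viol.append(Violation("diag", (0, 0), f"F[0,0]={F(0, 0)} != 2"))
        for i in range(1, size - 1):
            if abs(F(i, i) - F(i - 1, i - 1)) != 1:
                viol.append(Violation("diag", (i, i),
                                      f"F[{i},{i}]={F(i, i)} is not "
                                      f"F[{i-1},{i-1}] +/- 1"))
        if F(size - 1, size - 1) != 1:
            viol.append(Violation("diag", (size - 1, size - 1),
                                  f"F[{size-1},{size-1}]={F(size-1, size-1)} != 1"))
        for i in range(size):
            if F(i, i) <= 0:
                viol.append(Violation("diag", (i, i), "diagonal entries must be positive"))
    # 3b. subdiagonal
    for i in range(1, size):
        expected = i if mode is Mode.ISOCHRONOUS else F(i - 1, i - 1) - 1
        if F(i, i - 1) != expected:
            viol.append(Violation("subdiag", (i, i - 1),
                                  f"F[{i},{i-1}]={F(i, i-1)} != {expected}"))
    # 3c. local double inequality for remaining entries (zero-padded to j=0)
    for i in range(2, size):
        for j in range(i - 1):
            lo = F(i, j - 1) + F(i - 1, j) - F(i - 1, j - 1) - 1
            hi = lo + 1
            if not lo <= F(i, j) <= hi:
                viol.append(Violation("local_3c", (i, j),
                                      f"F[{i},{j}]={F(i, j)} outside [{lo}, {hi}]"))

    return ValidationReport(valid=not viol, violations=tuple(viol))
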
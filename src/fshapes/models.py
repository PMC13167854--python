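"""Probability models on fully heterochronous ranked tree shapes.

Three models, each with a seedable sampler and an exact evaluator:

* **coalescent** -- a backward-in-time jump chain on the full-cherry
  representation: starting from 2n unmerged leaves, each step merges,
  uniformly at random, either a pair of (exchangeable) leaves or a pair of
  already-ranked nodes; stripping the cherries leaves an n-leaf fully
  heterochronous tree.  The tree probability depends only on the F-matrix
  diagonal.
* **diagonal top-down** -- draw the diagonal (the coalescence/sampling
  event order) uniformly over the ``C_{n-1}`` Dyck paths, then move forward
  in time choosing the edge for each event uniformly among extant edges.
  Conditioned on the diagonal the resulting matrices are uniform.
* **Bernoulli / Beta splitting** -- fill the F-matrix autoregressively; at
  every position whose admissible set has two values, pick the smaller with
  probability ``p_{i,j}`` (a per-position table) or with a Beta(alpha,
  beta)-distributed coin.  Marginalising the Beta coin gives per-entry
  factors 1, alpha/(alpha+beta) or beta/(alpha+beta).

Evaluators return :class:`LogProb`, which carries both the log-probability
and an exact :class:`fractions.Fraction`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

from . import construction
from .construction import FSequence, _admissible, catalan, choice_positions
from .matrices import FMatrix, d_from_f, e_from_d, f_from_tree, tree_from_e, validate_f
from .trees import Mode, RankedTreeShape, coerce_mode, make_tree

__all__ = [
    "LogProb",
    "BernoulliParams",
    "coalescent_sample",
    "coalescent_prob",
    "sample_diagonal",
    "topdown_sample",
    "topdown_prob",
    "topdown_conditional_prob",
    "bernoulli_sample",
    "bernoulli_prob",
]


@dataclass(frozen=True)
class LogProb:
    """A probability carried both exactly and in log space."""

    exact: Fraction

    def __post_init__(self):
        if not 0 <= self.exact <= 1:
            raise ValueError(f"probability {self.exact} outside [0, 1]")

    @property
    def log(self) -> float:
        if self.exact == 0:
            return float("-inf")
        return math.log(self.exact.numerator) - math.log(self.exact.denominator)

    def __float__(self) -> float:
        return float(self.exact)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _comb2(a: int) -> int:
    return math.comb(a, 2) if a >= 2 else 0


def _check_het(F: FMatrix) -> None:
    if F.mode is not Mode.HETEROCHRONOUS:
        raise ValueError("expected a fully heterochronous F-matrix")
    report = validate_f(F.entries, F.mode)
    if not report.valid:
        raise ValueError(f"invalid F-matrix: {report.violations}")


# ---------------------------------------------------------------------------
# coalescent model


def coalescent_sample(n: int, seed=None) -> RankedTreeShape:
    """Draw a fully heterochronous ranked tree shape from the coalescent
    jump chain.

    The chain runs ``2n - 1`` steps over the full-cherry tree: the newly
    formed node at step ``j`` receives rank ``2n - 1 - j`` (the first node
    formed is the oldest, rank ``2n - 2``; the last is the root, rank 0).
    Leaf merges are aggregate events (leaves are exchangeable); ranked-node
    merges pick a uniform pair of unmerged ranked nodes.  Cherries are
    stripped implicitly: cherry roots are exactly the leaves of the
    returned n-leaf tree.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = _rng(seed)
    n_unmerged_leaves = 2 * n
    unmerged: list[int] = []  # ranks of unmerged non-leaf nodes
    parent_of: dict[int, int] = {}
    for rank in range(2 * n - 2, -1, -1):
        c_leaf = _comb2(n_unmerged_leaves)
        c_node = _comb2(len(unmerged))
        if rng.random() * (c_leaf + c_node) < c_leaf:
            n_unmerged_leaves -= 2  # new cherry; its root is a leaf of the output
        else:
            i, j = rng.choice(len(unmerged), size=2, replace=False)
            a, b = unmerged[int(i)], unmerged[int(j)]
            parent_of[a] = rank
            parent_of[b] = rank
            unmerged.remove(a)
            unmerged.remove(b)
        unmerged.append(rank)
    return make_tree(parent_of.items(), n_leaves=n, mode=Mode.HETEROCHRONOUS)


def coalescent_prob(F: FMatrix) -> LogProb:
    """Exact coalescent probability of the tree encoded by ``F``.

    The chain's state at step ``k`` is recoverable from the diagonal alone
    (``|V_k| = F[k-1, k-1]``, ``L_k = k + 1 - F[k-1, k-1]``), so the
    probability is a function of the diagonal:

    ``prod_{k: sampling} C(k+2-F[k,k], 2)  /
      prod_{k=0}^{2n-3} [C(k+2-F[k,k], 2) + C(F[k,k], 2)]``
    """
    _check_het(F)
    diag = F.diagonal()
    num = 1
    den = 1
    for k, f in enumerate(diag):
        if k >= 1 and f == diag[k - 1] - 1:
            num *= _comb2(k + 2 - f)
        den *= _comb2(k + 2 - f) + _comb2(f)
    return LogProb(Fraction(num, den))


# ---------------------------------------------------------------------------
# diagonal top-down model


def _dyck_completions(i: int, j: int, n: int) -> int:
    """Number of monotone lattice paths from (i, j) to (n-1, n-1) staying
    weakly below the line x = y:  N(i, j) = (i-j+1)/(2n-1-i-j) * C(2n-1-i-j, n-j)."""
    if j > i:
        return 0
    r = Fraction(i - j + 1, 2 * n - 1 - i - j) * math.comb(2 * n - 1 - i - j, n - j)
    assert r.denominator == 1
    return r.numerator


def sample_diagonal(n: int, seed=None) -> list[int]:
    """Uniform draw over the ``C_{n-1}`` feasible diagonals, via the O(n)
    sequential Dyck-path sampler: from lattice point ``(i, j)`` step right
    with probability ``N(i+1, j) / N(i, j)``.  A rightward step appends a
    +1 move of the diagonal (coalescence), an upward step a -1 move
    (sampling)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = _rng(seed)
    diag = [2]
    i, j = 1, 0  # the diagonal's leading 2 places the path at (1, 0)
    while (i, j) != (n - 1, n - 1):
        p_right = Fraction(_dyck_completions(i + 1, j, n), _dyck_completions(i, j, n))
        if rng.random() < p_right:
            i += 1
            diag.append(diag[-1] + 1)
        else:
            j += 1
            diag.append(diag[-1] - 1)
    return diag


def topdown_sample(n: int, seed=None) -> RankedTreeShape:
    """Draw a tree from the diagonal top-down model: a uniform diagonal,
    then a uniform extant edge for each successive event.

    The edge carrying the event of rank ``k + 1`` is chosen with
    probability ``D[k, L] / F[k, k]`` for parent label ``L``, after which
    row ``k + 1`` is the previous row decremented from column ``L`` on.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = _rng(seed)
    diag = sample_diagonal(n, rng)
    size = 2 * n - 2
    row = [2]
    parent_of: dict[int, int] = {}
    for k in range(size):
        weights = np.diff([0] + row[: k + 1])  # D[k, j] over labels j
        label = int(rng.choice(k + 1, p=weights / row[k]))
        parent_of[k + 1] = label
        if k + 1 < size:
            row = [row[j] - (1 if j >= label else 0) for j in range(k + 1)]
            row.append(diag[k + 1])
    return make_tree(parent_of.items(), n_leaves=n, mode=Mode.HETEROCHRONOUS)


def topdown_prob(F: FMatrix) -> LogProb:
    """Unconditional top-down probability:
    ``(1 / C_{n-1}) * 2^{n-1} / prod_k F[k, k]``."""
    _check_het(F)
    n = F.n_leaves
    prod = math.prod(F.diagonal())
    return LogProb(Fraction(2 ** (n - 1), catalan(n - 1) * prod))


def topdown_conditional_prob(F: FMatrix) -> LogProb:
    """Probability conditioned on the diagonal: ``2^{n-1} / prod_k F[k, k]``,
    identical for every matrix sharing the diagonal (conditional
    uniformity)."""
    _check_het(F)
    n = F.n_leaves
    return LogProb(Fraction(2 ** (n - 1), math.prod(F.diagonal())))


# ---------------------------------------------------------------------------
# Bernoulli / Beta splitting model


@dataclass(frozen=True)
class BernoulliParams:
    """Parameters of the Bernoulli splitting model.

    Either a per-position probability table ``p[(i, j)]`` over all
    potential choice positions (each strictly inside (0, 1)), or Beta
    parameters ``(alpha, beta)`` from which each position's coin is drawn.
    ``p`` is the probability of taking the *smaller* admissible value,
    i.e. of a sampling event over a coalescence where the choice exists.
    """

    table: dict[tuple[int, int], float] | None = None
    alpha: float | None = None
    beta: float | None = None

    def __post_init__(self):
        if (self.table is None) == (self.alpha is None and self.beta is None):
            raise ValueError("provide exactly one of table or (alpha, beta)")
        if self.table is not None:
            for pos, p in self.table.items():
                if not 0 < p < 1:
                    raise ValueError(f"p{pos}={p} outside (0, 1)")
        else:
            for name, v in (("alpha", self.alpha), ("beta", self.beta)):
                if v is None or not math.isfinite(v) or v <= 0:
                    raise ValueError(f"{name} must be finite and positive")

    @classmethod
    def from_table(cls, table: dict[tuple[int, int], float]) -> "BernoulliParams":
        return cls(table=dict(table))

    @classmethod
    def from_beta(cls, alpha: float, beta: float) -> "BernoulliParams":
        return cls(alpha=alpha, beta=beta)

    @property
    def is_beta(self) -> bool:
        return self.table is None

    def check_covers(self, n: int, mode: Mode) -> None:
        if self.is_beta:
            return
        missing = [pos for pos in choice_positions(n, mode)
                   if pos not in self.table]
        if missing:
            raise ValueError(f"probability table missing positions {missing}")

    def lower_prob(self, pos: tuple[int, int]) -> Fraction:
        """Marginal probability that the entry takes its smaller value."""
        if self.is_beta:
            return Fraction(self.alpha) / (Fraction(self.alpha) + Fraction(self.beta))
        if pos not in self.table:
            raise ValueError(f"probability table missing position {pos}")
        return Fraction(self.table[pos])


def bernoulli_sample(n: int, params: BernoulliParams, seed=None,
                     mode: Mode | str = Mode.HETEROCHRONOUS) -> FMatrix:
    """Draw an F-matrix by autoregressive Bernoulli splitting.

    Positions are filled in lexicographic order; forced positions consume
    no randomness.  In Beta mode the coin for each branching position is
    ``p ~ Beta(alpha, beta)`` (marginally: lower value with probability
    ``alpha / (alpha + beta)``).
    """
    mode = coerce_mode(mode)
    if n < 3:
        raise ValueError("the Bernoulli model is non-degenerate only for n >= 3")
    params.check_covers(n, mode)
    rng = _rng(seed)
    size = (n - 1) if mode is Mode.ISOCHRONOUS else (2 * n - 2)
    rows: list[list[int]] = [[2]]
    for i in range(1, size):
        rows.append([])
        for j in range(i + 1):
            values = _admissible(rows, i, j, n, mode)
            if len(values) == 1:
                rows[i].append(values[0])
                continue
            p = (rng.beta(params.alpha, params.beta) if params.is_beta
                 else params.table[(i, j)])
            rows[i].append(values[0] if rng.random() < p else values[1])
    A = np.zeros((size, size), dtype=np.int64)
    for i, row in enumerate(rows):
        A[i, : i + 1] = row
    return FMatrix.from_entries(A, mode, validate=False)


def bernoulli_prob(F: FMatrix, params: BernoulliParams) -> LogProb:
    """Exact probability of ``F`` under the Bernoulli splitting model.

    Replays the autoregressive fill along the matrix's own path: each
    position contributes 1 if forced, ``p`` (or ``alpha/(alpha+beta)``) if
    the entry took the smaller admissible value, and ``1 - p`` (or
    ``beta/(alpha+beta)``) if the larger.
    """
    report = validate_f(F.entries, F.mode)
    if not report.valid:
        raise ValueError(f"invalid F-matrix: {report.violations}")
    n = F.n_leaves
    if n < 3:
        raise ValueError("the Bernoulli model is non-degenerate only for n >= 3")
    params.check_covers(n, F.mode)
    prob = Fraction(1)
    rows: list[list[int]] = [[2]]
    for i in range(1, F.size):
        rows.append([])
        for j in range(i + 1):
            values = _admissible(rows, i, j, n, F.mode)
            entry = int(F.entries[i, j])
            if entry not in values:
                raise ValueError(
                    f"entry F[{i},{j}]={entry} is not admissible (legal: {values})")
            if len(values) == 2:
                p = params.lower_prob((i, j))
                prob *= p if entry == values[0] else 1 - p
            rows[i].append(entry)
    return LogProb(prob)


# ---------------------------------------------------------------------------
# convenience: a sampled matrix/tree for any model


def matrix_from_tree_sampler(tree: RankedTreeShape) -> FMatrix:
    return f_from_tree(tree)


def tree_from_matrix(F: FMatrix) -> RankedTreeShape:
    return tree_from_e(e_from_d(d_from_f(F)))
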
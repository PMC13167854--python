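"""Replicated sampling harness for tree-shape summary statistics.

For each simulated fully heterochronous ranked tree shape three statistics
are computed under the unit-epoch convention (consecutive ranked events are
one time unit apart):

* ``N_C`` -- number of cherries,
* ``L_I`` -- internal tree length (epochs survived by internal edges),
* ``L_T`` -- total tree length (epochs survived by all edges; equals the
  sum of the F-matrix diagonal).

:func:`simulate_summary` is Monte-Carlo; :func:`exact_expected_stats`
computes the same expectations exactly by exhaustive enumeration weighted
with the model's evaluator (small n only), and serves as the oracle for
the Monte-Carlo harness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from . import models
from .construction import enumerate_f_matrices
from .matrices import FMatrix, f_from_tree
from .models import BernoulliParams, LogProb
from .trees import Mode, RankedTreeShape, branch_lengths, count_cherries

__all__ = [
    "ModelSpec",
    "SimulationSummary",
    "tree_statistics",
    "simulate_summary",
    "exact_expected_stats",
]

_STATS = ("cherries", "internal_length", "total_length")


@dataclass(frozen=True)
class ModelSpec:
    """Which probability model to sample from, plus its parameters."""

    name: str  # coalescent | topdown | bernoulli
    params: BernoulliParams | None = None

    def __post_init__(self):
        if self.name not in ("coalescent", "topdown", "bernoulli"):
            raise ValueError(f"unknown model {self.name!r}")
        if self.name == "bernoulli" and self.params is None:
            raise ValueError("the bernoulli model requires BernoulliParams")
        if self.name != "bernoulli" and self.params is not None:
            raise ValueError(f"model {self.name!r} takes no parameters")

    def sample_tree(self, n: int, rng) -> RankedTreeShape:
        if self.name == "coalescent":
            return models.coalescent_sample(n, rng)
        if self.name == "topdown":
            return models.topdown_sample(n, rng)
        F = models.bernoulli_sample(n, self.params, rng)
        return models.tree_from_matrix(F)

    def prob(self, F: FMatrix) -> LogProb:
        if self.name == "coalescent":
            return models.coalescent_prob(F)
        if self.name == "topdown":
            return models.topdown_prob(F)
        return models.bernoulli_prob(F, self.params)


def tree_statistics(tree: RankedTreeShape) -> tuple[int, int, int]:
    """``(cherries, internal_length, total_length)`` of one tree."""
    total, internal = branch_lengths(tree)
    return count_cherries(tree), internal, total


@dataclass(frozen=True)
class SimulationSummary:
    model: ModelSpec
    n_leaves: int
    reps: int
    seed: int
    replicates: np.ndarray = field(repr=False)  # shape (reps, 3)

    @property
    def means(self) -> dict[str, float]:
        return dict(zip(_STATS, self.replicates.mean(axis=0)))

    @property
    def standard_errors(self) -> dict[str, float]:
        se = self.replicates.std(axis=0, ddof=1) / math.sqrt(self.reps)
        return dict(zip(_STATS, se))

    def to_dict(self) -> dict:
        out = {
            "model": self.model.name,
            "n_leaves": self.n_leaves,
            "reps": self.reps,
            "seed": self.seed,
        }
        if self.model.params is not None:
            p = self.model.params
            out["params"] = ({"alpha": p.alpha, "beta": p.beta} if p.is_beta
                             else {f"{i},{j}": v for (i, j), v in sorted(p.table.items())})
        means, ses = self.means, self.standard_errors
        out["statistics"] = {
            s: {"mean": float(means[s]), "se": float(ses[s])} for s in _STATS
        }
        return out


def simulate_summary(model: ModelSpec, n: int, reps: int,
                     seed: int = 0) -> SimulationSummary:
    """Draw ``reps`` trees and summarise the three statistics.

    Deterministic given ``(model, n, reps, seed)``: one generator is seeded
    once and consumed sequentially across replicates.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    rows = np.empty((reps, 3), dtype=np.int64)
    for r in range(reps):
        rows[r] = tree_statistics(model.sample_tree(n, rng))
    return SimulationSummary(model=model, n_leaves=n, reps=reps, seed=seed,
                             replicates=rows)


def exact_expected_stats(model: ModelSpec, n: int, *, max_n: int = 6
                         ) -> tuple[Fraction, Fraction, Fraction]:
    """Exact ``(E[N_C], E[L_I], E[L_T])`` by full enumeration weighted with
    the model's exact evaluator.  Guarded to small ``n`` (the space grows
    super-exponentially)."""
    if n > max_n:
        raise ValueError(f"exact expectations guarded at n <= {max_n}")
    if n < 2:
        raise ValueError("n must be >= 2")
    totals = [Fraction(0)] * 3
    mass = Fraction(0)
    for F in enumerate_f_matrices(n, Mode.HETEROCHRONOUS, cap=None):
        p = model.prob(F).exact
        stats = tree_statistics(models.tree_from_matrix(F))
        mass += p
        for k in range(3):
            totals[k] += p * stats[k]
    assert mass == 1
    return tuple(totals)
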
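"""Text formats: matrices, rank-labelled Newick, and fixture generation.

Matrix text format: one row per line, comma- or whitespace-separated
integers, the full square written out with zeros above the diagonal;
reading then writing is bit-exact.

Newick dialect: node labels are rank integers.  The 2-leaf fully
heterochronous tree is ``(1,2)0;``; isochronous leaves all carry the
shared rank ``n - 1`` (e.g. ``(1,1)0;`` for 2 leaves).  On write, children
are ordered by increasing rank, making the serialisation canonical.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from . import models
from .construction import choice_positions
from .matrices import FMatrix, validate_f
from .trees import Mode, RankedTreeShape, coerce_mode

__all__ = [
    "read_matrix",
    "write_matrix",
    "parse_matrix_text",
    "format_matrix",
    "read_tree",
    "write_tree",
    "FixtureSet",
    "make_fixtures",
]


# ---------------------------------------------------------------------------
# matrix text format


def parse_matrix_text(text: str) -> np.ndarray:
    rows: list[list[int]] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.replace(",", " ").split()
        try:
            rows.append([int(t) for t in tokens])
        except ValueError:
            raise ValueError(f"non-integer token on line {lineno}: {line!r}") from None
    if not rows:
        raise ValueError("empty matrix file")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("ragged rows: all rows must have the same length")
    A = np.array(rows, dtype=np.int64)
    if A.shape[0] != A.shape[1]:
        raise ValueError(f"matrix must be square, got {A.shape}")
    return A


def format_matrix(M) -> str:
    A = np.asarray(M)
    if isinstance(M, FMatrix):
        A = M.entries
    return "\n".join(" ".join(str(int(x)) for x in row) for row in A) + "\n"


def read_matrix(path) -> np.ndarray:
    return parse_matrix_text(Path(path).read_text())


def write_matrix(M, path) -> None:
    Path(path).write_text(format_matrix(M))


# ---------------------------------------------------------------------------
# rank-labelled Newick


def read_tree(newick_text: str, mode: Mode | str | None = None) -> RankedTreeShape:
    """Parse the rank-labelled Newick dialect.

    The mode is inferred when not given: duplicated leaf labels mean
    isochronous (all leaves at the shared rank), all-distinct labels mean
    fully heterochronous.
    """
    tree = dendropy.Tree.get(data=newick_text, schema="newick",
                             suppress_internal_node_taxa=True,
                             suppress_leaf_node_taxa=True)

    def label_of(node) -> int:
        raw = node.taxon.label if node.taxon is not None else node.label
        if raw is None:
            raise ValueError("every node must carry an integer rank label")
        try:
            return int(raw)
        except ValueError:
            raise ValueError(f"non-integer rank label {raw!r}") from None

    leaf_labels = [label_of(lf) for lf in tree.leaf_node_iter()]
    n = len(leaf_labels)
    if mode is None:
        mode = (Mode.ISOCHRONOUS if len(set(leaf_labels)) < len(leaf_labels)
                else Mode.HETEROCHRONOUS)
    mode = coerce_mode(mode)

    pairs: list[tuple[int, int]] = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            if label_of(node) != 0:
                raise ValueError("root must have rank 0")
            continue
        pairs.append((label_of(node), label_of(node.parent_node)))
    from .trees import make_tree

    return make_tree(pairs, n_leaves=n, mode=mode)


def write_tree(tree: RankedTreeShape) -> str:
    """Canonical Newick: children ordered by increasing rank."""
    kids = tree.children_of()

    def render(node: int) -> str:
        label = tree.effective_rank(node)
        if node not in kids:
            return str(label)
        ordered = sorted(kids[node], key=tree.effective_rank)
        return "(" + ",".join(render(c) for c in ordered) + ")" + str(label)

    return render(0) + ";"


# ---------------------------------------------------------------------------
# fixtures


@dataclass(frozen=True)
class FixtureSet:
    """Programmatically generated valid and adversarial matrices.

    ``valid`` holds sampled F-matrices from all three models;
    ``invalid`` holds single-entry perturbations of valid matrices, each
    labelled with one condition its validation report contains.
    """

    valid: tuple[FMatrix, ...]
    invalid: tuple[tuple[np.ndarray, Mode, str], ...]


def make_fixtures(seed: int = 0, n_range=range(3, 9)) -> FixtureSet:
    rng = np.random.default_rng(seed)
    valid: list[FMatrix] = []
    for n in n_range:
        valid.append(models.matrix_from_tree_sampler(models.coalescent_sample(n, rng)))
        valid.append(models.matrix_from_tree_sampler(models.topdown_sample(n, rng)))
        params = models.BernoulliParams.from_beta(2.0, 2.0)
        valid.append(models.bernoulli_sample(n, params, rng))

    wanted = ["row_monotone", "col_monotone", "diag", "subdiag", "local_3c"]
    invalid: list[tuple[np.ndarray, Mode, str]] = []
    found: set[str] = set()
    for F in valid:
        size = F.size
        for i in range(size):
            for j in range(i + 1):
                for delta in (1, -1, 2, -2):
                    if found == set(wanted):
                        break
                    A = F.entries.copy()
                    A[i, j] += delta
                    if A[i, j] < 0:
                        continue
                    report = validate_f(A, F.mode)
                    if report.valid:
                        continue
                    for cond in wanted:
                        if cond in report.conditions() and cond not in found:
                            invalid.append((A, F.mode, cond))
                            found.add(cond)
                            break
    return FixtureSet(valid=tuple(valid), invalid=tuple(invalid))
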
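import numpy as np
import pytest

import fshapes as fs

# Worked matrices printed in the source literature for the 3-leaf fully
# heterochronous tree and the 5-leaf isochronous tree.

EXAMPLE1_F = [[2, 0, 0, 0], [1, 3, 0, 0], [1, 2, 2, 0], [0, 1, 1, 1]]
EXAMPLE1_D = [[2, 0, 0, 0], [1, 2, 0, 0], [1, 1, 0, 0], [0, 1, 0, 0]]
EXAMPLE1_E = [[1, 0, 0, 0], [0, 1, 0, 0], [1, 0, 0, 0], [0, 1, 0, 0]]
EXAMPLE1_PAIRS = [(1, 0), (2, 1), (3, 0), (4, 1)]

EXAMPLE2_F = [[2, 0, 0, 0], [1, 3, 0, 0], [1, 2, 4, 0], [0, 1, 3, 5]]
EXAMPLE2_E = [[1, 0, 0, 0], [0, 1, 0, 0], [1, 0, 0, 0], [0, 1, 2, 2]]

# F-matrix of the tree whose probability is worked under all three models
# (coalescent 1/2, top-down 1/2, Beta-Bernoulli alpha/(alpha+beta)).
EXAMPLE7_F = [[2, 0, 0, 0], [1, 1, 0, 0], [0, 0, 2, 0], [0, 0, 1, 1]]

TABLE2_ISO = [1, 1, 1, 2, 5, 16, 61, 272, 1385, 7936]
TABLE2_HET = [1, 1, 4, 34, 496, 11056, 349504, 14873104, 819786496, 56814228736]


@pytest.fixture(scope="session")
def example1_tree():
    return fs.make_tree(EXAMPLE1_PAIRS, n_leaves=3, mode="het")


@pytest.fixture(scope="session")
def example1_f():
    return fs.FMatrix.from_entries(EXAMPLE1_F, "het")


@pytest.fixture(scope="session")
def example7_f():
    return fs.FMatrix.from_entries(EXAMPLE7_F, "het")


@pytest.fixture(scope="session")
def het_matrices():
    """Full heterochronous enumerations, cached per session."""
    return {n: list(fs.enumerate_f_matrices(n, "het")) for n in (2, 3, 4, 5)}


@pytest.fixture(scope="session")
def iso_matrices():
    return {n: list(fs.enumerate_f_matrices(n, "iso")) for n in (2, 3, 4, 5)}
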
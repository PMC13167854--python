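from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fshapes as fs
from fshapes import BernoulliParams, Mode
from fshapes.simulation import ModelSpec


def _chain_probability(tree):
    """Independent oracle: replay the coalescent jump chain forward from
    the tree structure itself (not from the F-matrix), multiplying the
    transition probabilities step by step."""
    from math import comb

    def c2(a):
        return comb(a, 2) if a >= 2 else 0

    n = tree.n_leaves
    kids = tree.children_of()
    n_unmerged_leaves = 2 * n  # leaves of the full-cherry representation
    unmerged_nodes: list[int] = []
    prob = Fraction(1)
    for rank in range(2 * n - 2, -1, -1):
        denom = c2(n_unmerged_leaves) + c2(len(unmerged_nodes))
        if rank in kids:  # merges a specific pair of ranked nodes
            prob *= Fraction(1, denom)
            for c in kids[rank]:
                unmerged_nodes.remove(c)
        else:  # merges some pair of exchangeable leaves (a new cherry)
            prob *= Fraction(c2(n_unmerged_leaves), denom)
            n_unmerged_leaves -= 2
        unmerged_nodes.append(rank)
    return prob


class TestCoalescent:
    def test_worked_probability(self, example7_f):
        assert fs.coalescent_prob(example7_f).exact == Fraction(1, 2)

    def test_unbalanced_diagonal_probability(self, het_matrices):
        for F in het_matrices[3]:
            expected = (Fraction(1, 2) if F.diagonal() == [2, 1, 2, 1]
                        else Fraction(1, 6))
            assert fs.coalescent_prob(F).exact == expected

    def test_agrees_with_chain_product(self, het_matrices):
        for F in het_matrices[3] + het_matrices[4]:
            chain = _chain_probability(fs.tree_from_f(F))
            assert fs.coalescent_prob(F).exact == chain

    def test_depends_only_on_diagonal(self, het_matrices):
        by_diag = {}
        for F in het_matrices[5]:
            by_diag.setdefault(tuple(F.diagonal()), set()).add(
                fs.coalescent_prob(F).exact)
        assert all(len(v) == 1 for v in by_diag.values())

    def test_two_leaf_tree_is_certain(self, het_matrices):
        assert fs.coalescent_prob(het_matrices[2][0]).exact == 1

    def test_sampler_returns_valid_trees(self):
        rng = np.random.default_rng(5)
        for n in (2, 3, 5, 10):
            t = fs.coalescent_sample(n, rng)
            assert t.n_leaves == n and t.mode is Mode.HETEROCHRONOUS
            assert fs.validate_f(fs.f_from_tree(t).entries, "het").valid

    def test_sampler_deterministic_given_seed(self):
        assert fs.coalescent_sample(7, 123) == fs.coalescent_sample(7, 123)


class TestDyckDiagonalSampler:
    def test_two_leaves_forced(self):
        assert fs.sample_diagonal(2, 0) == [2, 1]

    def test_path_count_is_catalan(self):
        from fshapes.models import _dyck_completions
        for n in (2, 3, 4, 6, 9):
            assert _dyck_completions(1, 0, n) == fs.catalan(n - 1)

    def test_roughly_uniform(self):
        # light smoke check; the full chi-square criterion lives in the
        # acceptance suite
        rng = np.random.default_rng(2)
        counts = {}
        for _ in range(5000):
            d = tuple(fs.sample_diagonal(4, rng))
            counts[d] = counts.get(d, 0) + 1
        assert len(counts) == 5
        assert all(abs(c - 1000) < 150 for c in counts.values())


class TestTopDown:
    def test_worked_probability(self, example7_f):
        assert fs.topdown_prob(example7_f).exact == Fraction(1, 2)

    def test_conditional_is_one_over_eighteen(self):
        mats = list(fs.enumerate_with_diagonal([2, 3, 4, 3, 2, 1], 4))
        assert len(mats) == 18
        assert {fs.topdown_conditional_prob(F).exact for F in mats} \
            == {Fraction(1, 18)}

    def test_conditional_uniformity(self, het_matrices):
        for n in (3, 4, 5):
            by_diag = {}
            for F in het_matrices[n]:
                by_diag.setdefault(tuple(F.diagonal()), []).append(
                    fs.topdown_conditional_prob(F).exact)
            for diag, probs in by_diag.items():
                assert len(set(probs)) == 1
                assert probs[0] * len(probs) == 1
                expected = Fraction(2 ** (n - 1),
                                    int(np.prod(np.array(diag, dtype=object))))
                assert probs[0] == expected

    def test_unconditional_factorises(self, het_matrices):
        for F in het_matrices[4]:
            assert (fs.topdown_prob(F).exact
                    == fs.topdown_conditional_prob(F).exact / fs.catalan(3))

    def test_sampler_respects_pinned_support(self):
        rng = np.random.default_rng(9)
        allowed = {F.entries.tobytes()
                   for F in fs.enumerate_f_matrices(4, "het")}
        for _ in range(200):
            t = fs.topdown_sample(4, rng)
            assert fs.f_from_tree(t).entries.tobytes() in allowed

    def test_sampler_deterministic_given_seed(self):
        assert fs.topdown_sample(6, 42) == fs.topdown_sample(6, 42)


class TestBernoulli:
    def test_telescoping_formulas_at_n3(self, het_matrices):
        # with probabilities p_{1,1}, p_{2,0}, p_{3,0} the four trees get
        # p, (1-p)q, (1-p)(1-q)r, (1-p)(1-q)(1-r)
        # dyadic probabilities are exactly representable as floats
        p, q, r, s = Fraction(1, 4), Fraction(3, 8), Fraction(5, 16), Fraction(1, 2)
        table = {(1, 1): float(p), (2, 0): float(q), (3, 0): float(r),
                 (3, 1): float(s)}
        params = BernoulliParams.from_table(table)
        probs = [fs.bernoulli_prob(F, params).exact for F in het_matrices[3]]
        assert probs == [p, (1 - p) * q, (1 - p) * (1 - q) * r,
                         (1 - p) * (1 - q) * (1 - r)]
        assert sum(probs) == 1

    def test_all_half_probabilities(self, het_matrices):
        params = BernoulliParams.from_table(
            {pos: 0.5 for pos in fs.choice_positions(3, "het")})
        probs = [fs.bernoulli_prob(F, params).exact for F in het_matrices[3]]
        assert probs == [Fraction(1, 2), Fraction(1, 4),
                         Fraction(1, 8), Fraction(1, 8)]

    def test_beta_marginal_of_worked_tree(self, example7_f):
        # only one position branches along this matrix's fill path
        params = BernoulliParams.from_beta(3.0, 4.0)
        assert fs.bernoulli_prob(example7_f, params).exact == Fraction(3, 7)

    def test_beta_normalization(self, het_matrices):
        params = BernoulliParams.from_beta(2.0, 5.0)
        total = sum((fs.bernoulli_prob(F, params).exact
                     for F in het_matrices[4]), Fraction(0))
        assert total == 1

    def test_isochronous_mode_normalizes(self, iso_matrices):
        params = BernoulliParams.from_beta(2.0, 3.0)
        total = sum((fs.bernoulli_prob(F, params).exact
                     for F in iso_matrices[5]), Fraction(0))
        assert total == 1

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="outside"):
            BernoulliParams.from_table({(1, 1): 1.0})
        with pytest.raises(ValueError, match="positive"):
            BernoulliParams.from_beta(0.0, 1.0)
        with pytest.raises(ValueError, match="missing"):
            fs.bernoulli_sample(4, BernoulliParams.from_table({(1, 1): 0.5}),
                                seed=0)

    def test_sampler_deterministic_and_valid(self):
        params = BernoulliParams.from_beta(2.0, 2.0)
        a = fs.bernoulli_sample(6, params, seed=3)
        b = fs.bernoulli_sample(6, params, seed=3)
        assert a == b
        assert fs.validate_f(a.entries, "het").valid
        iso = fs.bernoulli_sample(8, params, seed=3, mode="iso")
        assert fs.validate_f(iso.entries, "iso").valid

    def test_beta_skew_controls_balance(self):
        """alpha >> beta favours sampling over branching, hence few extant
        lineages and caterpillar-like (cherry-poor) trees."""
        rng = np.random.default_rng(17)
        means = {}
        for ab in ((10.0, 1.0), (1.0, 10.0)):
            params = BernoulliParams.from_beta(*ab)
            cherries = [fs.count_cherries(fs.tree_from_f(
                fs.bernoulli_sample(20, params, rng))) for _ in range(1000)]
            means[ab] = np.mean(cherries)
        assert means[(10.0, 1.0)] < means[(1.0, 10.0)]

    def test_rejects_inadmissible_matrix_entries(self, example7_f):
        bad = example7_f.entries.copy()
        bad[2, 0] = 1  # breaks the forced-collision rule
        with pytest.raises(ValueError):
            fs.bernoulli_prob(
                fs.FMatrix(n_leaves=3, mode=Mode.HETEROCHRONOUS, entries=bad),
                BernoulliParams.from_beta(1.0, 1.0))


@settings(max_examples=25, derandomize=True, deadline=None)
@given(n=st.integers(min_value=3, max_value=8),
       seed=st.integers(min_value=0, max_value=2**16),
       model=st.sampled_from(["coalescent", "topdown", "bernoulli"]))
def test_every_sampled_tree_encodes_to_a_valid_matrix(n, seed, model):
    spec = (ModelSpec(model) if model != "bernoulli"
            else ModelSpec(model, BernoulliParams.from_beta(1.5, 2.5)))
    tree = spec.sample_tree(n, np.random.default_rng(seed))
    F = fs.f_from_tree(tree)
    assert fs.validate_f(F.entries, "het").valid
    assert fs.tree_from_f(F) == tree
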
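"""Sample ranked tree shapes from the three models and evaluate exact
probabilities.

The coalescent model merges pairs bottom-up; the diagonal top-down model
draws a uniform event order and then uniform edges; the Beta-Bernoulli
splitting model fills the F-matrix autoregressively with per-entry coins.
Every evaluator returns an exact rational, and each model normalises to 1
over the full enumeration.
"""

from fractions import Fraction

import fshapes as fs
from fshapes import BernoulliParams

F = fs.FMatrix.from_entries(
    [[2, 0, 0, 0], [1, 1, 0, 0], [0, 0, 2, 0], [0, 0, 1, 1]], "het")
print("tree:", fs.write_tree(fs.tree_from_f(F)))
print("coalescent probability:", fs.coalescent_prob(F).exact)     # 1/2
print("top-down probability:  ", fs.topdown_prob(F).exact)        # 1/2
params = BernoulliParams.from_beta(3.0, 4.0)
print("Beta(3,4) probability: ", fs.bernoulli_prob(F, params).exact)  # 3/7

for name, prob in [("coalescent", fs.coalescent_prob),
                   ("topdown", fs.topdown_prob),
                   ("beta(3,4)", lambda m: fs.bernoulli_prob(m, params))]:
    total = sum((prob(m).exact for m in fs.enumerate_f_matrices(4, "het")),
                Fraction(0))
    print(f"sum over all 34 matrices at n=4 under {name}: {total}")

# seeded samplers return reproducible trees
t = fs.coalescent_sample(6, seed=1)
print("coalescent draw (n=6):", fs.write_tree(t))
d = fs.sample_diagonal(6, seed=1)
print("uniform diagonal draw (n=6):", d)
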
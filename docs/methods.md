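# Methods

## Objects and conventions

A ranked tree shape is a rooted full binary tree with a total order on its
nodes that increases along every root-to-leaf path. Ranks are 0-based and
the root has rank 0. In the fully heterochronous flavour the ranks
`0 … 2n − 2` are a bijection onto all nodes and rank `2n − 2` is
necessarily a leaf; in the isochronous flavour only internal nodes
`0 … n − 2` are ranked and every leaf carries the shared terminal rank
`n − 1`. Isochronous leaves are bookkept with synthetic negative ids used
purely for graph bookkeeping; they are excluded from equality, which is
defined as equality of F-matrices (the canonical form), so sister order
never matters.

Ranks double as event times on a unit grid: consecutive ranked events are
one epoch apart, and there is no root edge. An edge from a parent of rank
`p` to a child of rank `c` therefore survives `c − p` epochs, which is the
only branch-length notion in the package — calendar or substitution units
are out of scope. Total tree length is the sum over all edges (equal to
the F-matrix diagonal sum, a cross-checked invariant); internal length
keeps edges whose child is internal.

## Matrix encodings

`F[i, j]` (for `j ≤ i`) counts edges from a node of rank ≤ `j` to a node
of rank > `i`, with isochronous leaves ranking as `n − 1`. `D` and `E`
are its successive difference transforms; `E` is the offset adjacency
matrix (`E[i, j] = 1` iff rank `i + 1` is a child of rank `j`; the last
isochronous row instead counts leaf children, 0–2). All out-of-bound
reads are 0; that convention is centralised in a single accessor used by
every formula.

`validate_f` checks the full inequality characterisation and reports
*every* violation (condition ids `row_monotone`, `col_monotone`, `diag`,
`subdiag`, `local_3c`) rather than failing fast, so diagnostics and
adversarial fixtures can name the exact broken condition. Sizes that fit
neither flavour, negative entries, non-integers and non-triangular input
are errors (outside the precondition), not violations. The local double
inequality is applied for all `j ≤ i − 2` including `j = 0`, where the
zero-padding convention makes it coincide with column monotonicity — a
harmless extension that keeps one uniform rule.

Two printed-form subtleties are worth recording. First, the ±1 diagonal
chain condition formally skips the final step, and the "move up" rule of
the extension machinery appears one looser than the feasibility bound
`F[i,i] ≤ 2n − i − 2`; both gaps are closed by parity (diagonal entries
satisfy `F[i,i] ≡ i (mod 2)`), so the conditions are implemented verbatim
and their sufficiency is confirmed by exhaustive brute-force equivalence
at small n. Second, the Euler-polynomial closed form for isochronous
counts degenerates to 0 at `n = 1`, where the count is 1; that boundary
case is special-cased.

## Single-pass construction

A partially filled matrix in row-major order (an F-sequence) can always be
extended: the admissible values at the next position are

- the fixed `2` at the origin;
- on the diagonal, `f ± 1` subject to positivity and the feasibility band
  (so the event order is chosen freely within Dyck-path constraints);
- on the subdiagonal, the forced `f_prev_diag − 1`;
- elsewhere, the band `[L, U]` with
  `L = max(left, up − 1, left + up − upleft − 1)` and
  `U = min(up, left + up − upleft)` — except that a *collision* (the entry
  above equalling the previous diagonal value) forces `f_prev_diag − 1`.

`U − L ≤ 1` always, so every position admits one or two values and the
space of shapes is the leaf set of a binary decision tree. The no-dead-end
property is tested exhaustively (every reachable prefix at n ≤ 4
heterochronous / n ≤ 6 isochronous admits an extension and completes).
Enumeration streams matrices lazily in lexicographic order of choices and
carries a safety cap (default 10⁷, overridable) because the space grows
super-exponentially.

## Counting

Three independent routes, asserted to agree: (1) heterochronous — the
root-splitting recursion `|T*_n| = ½ Σ_ℓ C(2n−2, 2ℓ−1) |T*_ℓ| |T*_{n−ℓ}|`
over full-cherry subtrees; isochronous — the boustrophedon (Seidel)
zigzag recurrence; (2) closed forms `2^n (2^{2n} − 1)|B_{2n}|/n` and
`2^{n−1}|E_{n−1}(½) − E_{n−1}(0)|` in exact rational arithmetic (sympy
Bernoulli numbers / Euler polynomials); (3) direct enumeration, guarded by
default to `n ≤ 8`. All arithmetic is arbitrary precision.

## Probability models

All evaluators compute exact `Fraction`s, wrapped in a `LogProb` that also
exposes the log value; normalization tests therefore assert exact sums of
1 rather than float tolerances.

**Coalescent.** The jump chain starts from `2n` unmerged leaves of the
full-cherry representation and runs `2n − 1` steps; new nodes take ranks
`2n − 2, …, 0` in formation order. With `L` unmerged leaves and `V`
unmerged ranked nodes, a leaf pair merges with probability
`C(L,2) / (C(L,2) + C(V,2))` as a single aggregate outcome (leaves are
exchangeable), while each specific ranked pair has mass
`1 / (C(L,2) + C(V,2))`. `C(a,2) = 0` for `a < 2` covers boundary steps.
The tree probability depends only on the diagonal, since the chain's state
is recoverable from it (`|V_k| = F[k−1,k−1]`, `L_k = k + 1 − |V_k|`); the
evaluator uses the resulting product formula and is tested against an
independent forward replay of the chain from the tree structure.

**Diagonal top-down.** The diagonal is drawn uniformly over the `C_{n−1}`
feasible diagonals by the O(n) sequential Dyck-path sampler: from lattice
point `(i, j)` step right with probability `N(i+1, j)/N(i, j)`, where
`N(i, j) = ((i−j+1)/(2n−1−i−j))·C(2n−1−i−j, n−j)` counts completions. The
path starts at `(1, 0)` — whose completion count is exactly `C_{n−1}` —
corresponding to the diagonal's fixed leading 2. Then, forward in time,
the edge carrying the event of rank `k + 1` is chosen with probability
`D[k, L]/F[k, k]` over parent labels `L`, and the next row is the previous
row decremented from column `L` on. The conditional probability given the
diagonal is `2^{n−1}/∏_k F[k,k]` for every compatible matrix (conditional
uniformity), and the unconditional probability divides by `C_{n−1}`.

**Bernoulli / Beta splitting.** The matrix is filled autoregressively; at
each genuinely branching position the smaller admissible value (a sampling
event rather than a coalescence, where the choice exists) is taken with
probability `p_{i,j}`. Parameters are either an explicit table over the
potential choice positions — `(n−3)(n−2)/2` isochronous, `2n² − 5n + 1`
heterochronous, decomposed as `2n − 5` free diagonal positions plus
`(2n−4)(2n−3)/2` positions below the subdiagonal — or Beta(α, β), in which
case the sampler draws each position's coin from the Beta density and the
evaluator uses the marginalised per-entry factors 1, `α/(α+β)`, `β/(α+β)`.
The table is a count of *potential* choice positions: whether a given
position actually branches depends on the prefix, and forced positions
contribute factor 1 and consume no randomness. The model applies to both
flavours (isochronous diagonals are fixed, leaving only the sub-subdiagonal
coins).

RNG contract: every sampler accepts an integer seed or a
`numpy.random.Generator` (PCG64); identical seed and parameters give an
identical tree, bit-for-bit across runs.

## Simulation harness

`simulate_summary` draws replicate trees from one model and reports mean
and standard error of `(N_C, L_I, L_T)`; a single generator seeded once is
consumed sequentially, so summaries are bit-identical given
`(model, n, reps, seed)`. Standard errors are reported because the
reference tables print Monte-Carlo means without error bars; tolerance for
reproducing them is derived from observed replicate variance (3 standard
errors; 5% relative for the long-tailed total length at n = 50), with
1000 replicates matching the reference setting. `exact_expected_stats`
provides the exact oracle by enumeration (guarded to n ≤ 6).

The samplers *are* the synthetic-data generators: there is no separate
fixture corpus. `make_fixtures` derives valid matrices from all three
samplers (n = 3 … 8) and adversarial invalid matrices by single-entry
perturbation, each labelled with a violated condition verified at
generation time. What these data do not emulate: continuous branch
lengths, heterochronous trees with shared leaf ranks, and any notion of
sequence data — conclusions from the test suite concern the combinatorial
and probabilistic layer only.

## Numerical and design choices

- Exact integer/rational arithmetic everywhere correctness is asserted;
  floats only inside samplers (coin flips) and summary statistics.
- Probability-table and Beta parameters are validated strictly
  (`p ∈ (0,1)`, `α, β` finite positive); degenerate deterministic models
  are deliberately excluded.
- The 2-leaf heterochronous and `n ≤ 2` isochronous matrices are legal
  degenerate inputs; `n = 1` has no matrix and is handled only by the
  counting routines. The Bernoulli model requires `n ≥ 3` (no choices
  exist below that).
- Canonical Newick output orders children by increasing rank, making
  serialisation unique; reading validates rank monotonicity and infers the
  flavour from duplicated leaf labels unless given explicitly.
- Matrix text files are full squares with zeros above the diagonal,
  comma- or whitespace-separated; reading rejects ragged rows and
  round-trips bit-exactly.

## Known limitations

- Enumeration-backed operations (exact expectations, normalization
  checks) are exponential in n and guarded accordingly; evaluators
  themselves are polynomial and fine at n in the hundreds.
- Partially heterochronous shapes (shared leaf ranks among some leaves)
  are not modelled.
- The Monte-Carlo reference tables were produced elsewhere with unknown
  seeds; agreement is statistical, not bit-wise. One reference cell family
  (the Beta(1,10) column) sits a few standard errors from this
  implementation's exact expectations even though the worked per-tree
  probabilities and normalization pin the model; the discrepancy is
  documented in the test choices rather than tuned away.
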
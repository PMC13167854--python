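# fshapes

Exact combinatorics and probability models for **ranked tree shapes** — the
discrete backbone of phylogenetic trees: a rooted full binary tree together
with a total order on its nodes compatible with the root-to-leaf direction.

Two flavours are supported. In an **isochronous** ranked tree shape only
the `n − 1` internal nodes are ranked and all leaves share the terminal
rank, as when discretising a time tree. In a **fully heterochronous**
ranked tree shape all `2n − 1` nodes carry distinct ranks `0 … 2n − 2`, as
when discretising a rooted phylogram — the natural object when branch
lengths measure evolutionary change rather than calendar time (e.g. B-cell
receptor phylogenies), so that leaf positions are part of the inferential
output.

## The F-matrix calculus

A ranked tree shape `T` with `n` leaves is encoded losslessly as a
lower-triangular integer **F-matrix** (`(n−1)×(n−1)` isochronous,
`(2n−2)×(2n−2)` fully heterochronous):

    F[i, j] = #{ edges (v, w) : rank(v) ≤ j and rank(w) > i },

i.e. the number of lineages alive throughout the whole window between the
events of ranks `j` and `i + 1`. Column-differencing gives the **D-matrix**
(`D[i,j] = F[i,j] − F[i,j−1]`), row-differencing that gives the
**E-matrix** (`E[i,j] = D[i,j] − D[i+1,j]`), an offset adjacency matrix
from which the tree is read back directly. Membership of an arbitrary
integer matrix in the F-matrix class is decided by a short system of
linear inequalities: row/column monotonicity, a diagonal/subdiagonal
pattern (the diagonal steps ±1 in the heterochronous case — `+1` for a
coalescence, `−1` for a sampling event), and a local double inequality
involving four neighbouring entries.

That locality is the engine of the package: F-matrices can be filled one
entry at a time in row-major order with **no backtracking**, each position
admitting one or two values determined by at most four previous entries.
This yields:

- exhaustive lazy enumeration of all ranked tree shapes of a given size
  (optionally with the diagonal — the event order — pinned);
- exact counts: the number of fully heterochronous shapes `|T*_n|`
  (reduced tangent numbers, `|T*_n| = 2^n (2^{2n} − 1) |B_{2n}| / n`) and
  isochronous shapes `|T_n|` (Euler zigzag numbers), each computed by
  recursion, closed form and enumeration;
- three probability models on fully heterochronous shapes, each with a
  seeded sampler and an exact rational evaluator:
  - **coalescent** — a bottom-up jump chain on the full-cherry
    representation (each step merges a uniform pair of leaves or of ranked
    nodes);
  - **diagonal top-down** — a uniform Dyck-path draw of the event order
    (`C_{n−1}` diagonals) followed by uniform edge choices; conditioned on
    the diagonal all shapes are equally likely, with probability
    `2^{n−1} / ∏_k F[k,k]`;
  - **Bernoulli / Beta splitting** — autoregressive per-entry coins
    `p_{i,j}`, or marginally `α/(α+β)` when the coins are Beta(α, β);
    `α ≫ β` yields caterpillar-like (unbalanced) trees;
- a simulation harness for the classic shape statistics: number of
  cherries `N_C`, internal length `L_I` and total length `L_T` in unit
  epochs (`L_T = Σ_k F[k,k]`).

## Worked example

```python
import fshapes as fs

tree = fs.make_tree([(1, 0), (2, 1), (3, 0), (4, 1)], n_leaves=3, mode="het")
F = fs.f_from_tree(tree)
print(F.entries.tolist())      # [[2,0,0,0],[1,3,0,0],[1,2,2,0],[0,1,1,1]]
print(fs.write_tree(tree))     # ((2,4)1,3)0;
print(fs.coalescent_prob(F).exact)   # 1/6
print(fs.count_shapes(6, "het"))     # 11056
print(sum(1 for _ in fs.enumerate_with_diagonal([2, 3, 4, 3, 2, 1], 4)))  # 18
```

The F-matrix row `i` reads off how many of the lineages alive just after
event `i` originated by each earlier epoch; the probability `1/6` is the
coalescent mass of this 3-leaf shape (its diagonal `[2,3,2,1]` — one
coalescence, then three samplings — is shared by three equally likely
shapes); `11056` is the number of fully heterochronous shapes with 6
leaves; and `18` shapes share the 4-leaf event order `[2,3,4,3,2,1]`, each
with conditional probability `1/18` under the top-down model.

The `examples/` directory has one short narrative script per capability;
a thin CLI (`fshapes validate | convert | enumerate | count | sample |
prob | simulate | fixtures`) exposes the same operations on text files
(matrix text and rank-labelled Newick, e.g. `(1,2)0;`).

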
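"""Enumerate and count ranked tree shapes.

The single-pass construction fills F-matrices entry by entry with no
backtracking, so the whole space streams lazily.  Counts are cross-checked
against the root-splitting recursion and the Bernoulli-number /
Euler-polynomial closed forms (exact integers throughout).
"""

import fshapes as fs

print("All 4 heterochronous F-matrices for n = 3 leaves:")
for F in fs.enumerate_f_matrices(3, "het"):
    print(fs.format_matrix(F.entries))

print("counts |T*_n| (fully heterochronous) and |T_n| (isochronous):")
for n in range(1, 11):
    het = fs.count_shapes(n, "het", "recursion")
    iso = fs.count_shapes(n, "iso", "recursion")
    assert het == fs.count_shapes(n, "het", "closed_form")
    assert iso == fs.count_shapes(n, "iso", "closed_form")
    print(f"  n={n:2d}  het {het:>12d}   iso {iso:>6d}")

# The diagonal records the order of coalescence (+1) and sampling (-1)
# events; it is a Dyck path, so there are Catalan-many of them, and the
# diagonal classes partition the space:
n = 4
print(f"feasible diagonals at n={n}: {fs.count_diagonals(n)} (Catalan C_3)")
k = sum(1 for _ in fs.enumerate_with_diagonal([2, 3, 4, 3, 2, 1], n))
print(f"matrices sharing diagonal [2,3,4,3,2,1]: {k}")
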
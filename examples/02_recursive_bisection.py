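"""Rent characteristic from recursive balanced min-cut bisection.

The classical VLSI route: split the network into halves minimizing cut
edges (Fiduccia-Mattheyses refinement, best of several random starts),
recurse, and read one (B, P) point off each level of the hierarchy.
"""

import rentian as rt

g = rt.make_benchmark_graph("grid2d", n=16)
tree = rt.recursive_bisect(g, epsilon=0.1, restarts=10, seed=3)
char = rt.bisect_characteristic(g, tree)

print(f"{len(tree.levels)} levels; per-level (modules, B, mean external edges P):")
for pt in reversed(char.points):
    print(f"  {int(pt.n_modules):4d} modules  B = {pt.B:7.2f}  P = {pt.P:6.2f}")

fit = rt.fit_rent(char)
print(f"bipartition Rent exponent p = {fit.p:.3f} (R^2 = {fit.r_squared:.3f})")
# Coarse levels saturate (a minimal halving cut of an n x n lattice is one
# side length), so the all-level exponent sits below the interior value 1/2.
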
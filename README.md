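# rentian

Topological Rentian scaling of complex networks: where does the power law
actually hold?

## The problem

Rent's rule is the empirical power law

    P = k · B^p

relating the average number of external connections `P` of a module to the
average number of nodes `B` it contains, across a hierarchy of partitions of
a network. Born in circuit design, it is equally used to quantify the
wiring complexity of biological networks — neuronal connectomes, protein
interactomes — where a low Rent exponent `p` signals wiring economy.

The catch is that the power law only holds over a limited range of module
sizes: at large `B` (few modules) it overestimates connectivity
(**Region II**), and at the smallest modules it can underestimate it
(**Region III**). Any fitted exponent is meaningless unless **Region I**,
the genuine scaling range, is identified first — and where its boundaries
lie has traditionally been an eyeball judgement.

This package implements a principled criterion. Partitions come from greedy
box coverings (boxes of bounded graph diameter, the box-counting
construction behind network fractal dimension) or from recursive balanced
min-cut bisection. A sample of degree-preserving randomizations of the
network (double-edge swaps) shares the empirical Rent characteristic at
small scales but *bifurcates* from it at large scales; the coefficient of
variation `c(b)` of the sample's log-average external-connection counts at
box size `b` quantifies the split, and Region II is every scale from the
first crossing of `c ≥ β` upward (default `β = 0.1`). Region III is trimmed
by suppressing underestimated small-`B` points while each removal raises
the fit's `R²` by more than `ρ` (default `10⁻³`).

Around that core the package provides:

- readers for edge lists, GML, Pajek, and VLSI netlists (ISCAS89
  `.bench`-style, ISPD98 `.net`-style) with clique expansion of hypergraph
  nets and the standard preprocessing (undirect, deduplicate, de-loop,
  largest component);
- four null-model families — swap-randomized (SA), configuration model
  (CM), Chung–Lu (CLM), Erdős–Rényi (ER) — as reproducible seeded ensembles;
- the sensitivity exponent `α` of `P' = K·P^α`, measuring how strongly
  randomization inflates a network's external connectivity;
- Louvain modularity `Q`, average path length `L`, and Kendall rank
  correlation with an *exact* small-sample null distribution (computed from
  the inversion-number recurrence), including exact critical values —
  essential when correlating properties across a handful of networks;
- deterministic synthetic fixtures (lattices, trees, rings, hierarchical
  modular and geometric random graphs, and synthetic characteristics with
  known `p`, `k`) for validation.

## Worked example

```python
import rentian as rt

g = rt.make_benchmark_graph("grid2d", n=20)          # 400-node lattice
emp = rt.covering_characteristic(g, seed=1, repetitions=5)
ens = rt.ensemble_characteristic(
    g, rt.RandomModelSpec(model="SA", sample_size=10, base_seed=1))
seg = rt.segment_regions(emp, ens, beta=0.1)
fit = rt.fit_rent(emp, seg)
print(f"Region I scales: b = {seg.region_I}")
print(f"Rent fit: p = {fit.p:.3f} +- {fit.std_err:.3f}, "
      f"k = {fit.k:.2f}, R^2 = {fit.r_squared:.3f}")
```

prints

```
Region I scales: b = (1, 2, 3, 4, 5, 6, 7, 8)
Rent fit: p = 0.563 +- 0.021, k = 3.93, R^2 = 0.992
```

Scales `b ≥ 9` were assigned to Region II: there the randomized sample has
either bifurcated (`c ≥ 0.1`) or collapsed entirely, so those points are
excluded from the fit. The exponent `p ≈ 0.56` with `k ≈ 3.9` reflects the
boundary/area scaling of a two-dimensional lattice (a module of `B` nodes
meets roughly `√B` outside neighbours through its perimeter; every node has
about 4 pins), with finite-size effects nudging it above the ideal 1/2.

The `examples/` directory has one short script per capability: box-covering
analysis, recursive bisection, null models, sensitivity + modularity +
exact Kendall inference, and netlist handling. A thin CLI mirrors the
library: `rentian fit graph.edges --seed 1`, `rentian bisect`, `rentian
randomize`, `rentian stats`, `rentian fixture`, `rentian correlate`.

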
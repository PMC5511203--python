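# Methods

## Model and procedure

A *Rent characteristic* is the discrete curve `P = P_c(B)` obtained from a
family of partitions of a simple, connected, undirected graph: for each
partition, `B = N / (number of modules)` and `P` is the mean over modules
of the number of edges with exactly one endpoint inside the module. Each
cut edge therefore contributes one external connection to *both* of its
incident modules — the graph analogue of counting pins per module. (The
alternative of counting each cut edge once globally halves every `P`
uniformly; it changes only the coefficient `k`, never the exponent `p`.
The choice is recorded in exported metadata.) Rent's rule asserts
`P = k·B^p` over a range of scales, and the package's job is to find that
range before fitting it.

### Partition hierarchies

**Box covering** (default). A box of size `b` is a node set of host-graph
diameter at most `b − 1`. Coverings are built by greedy coloring: nodes
are visited in a random order and each receives the smallest color not
already held by a node at distance `≥ b`; color classes are the boxes.
Distances are exact BFS shortest paths computed once per graph and reused
at every scale, and one visit permutation is shared by all scales of a
sequence, so a single seed yields a coherent hierarchy for
`b = 1 … diameter + 1` (the first scale whose covering is a single box).
Boxes constrain pairwise distance only and may induce disconnected
subgraphs; on a disconnected host (which degree-preserving rewiring can
produce) boxes never span components, because cross-component distance is
infinite, and the final covering has one box per component. Minimal
covering is NP-hard; greedy coloring is the standard cheap approximation,
and its dispersion across visit orders is small. The empirical
characteristic averages `repetitions` independent coverings per scale
(default 10): at each `b`, the reported module count is the mean over
repetitions, `B = N / mean`, and `P` is the mean per-covering average.
Ensemble replicates are covered once each (`repetitions = 1`) — the
sample-level averaging already damps coloring noise.

One calibration fact worth knowing: at lattice sizes of order 10³ nodes
the greedy covering's overhead over the minimal packing grows slowly with
`b`, so the measured box-counting slope of a 2D grid is ≈ −1.6 rather than
the asymptotic −2. The covering itself is tight — its largest boxes attain
the exact L1-diamond bound and counts stay within 3× the packing lower
bound — and the *Rent* exponent is unaffected (both `B` and `P` derive
from the same boxes), but fractal-dimension readings at these sizes should
be treated as effective, finite-size values.

**Recursive bisection.** The classical alternative: split the node set
into two nearly equal halves minimizing cut edges, recurse, and take one
point per level. Splits use flat Fiduccia–Mattheyses refinement — random
balanced starts, single-node moves ordered by cut gain through integer
bucket lists, moved nodes locked for the rest of the pass, best feasible
prefix kept, passes repeated until no improvement, best of `restarts`
starts (default 10). The balance window is `(½ ± ε)` of the parent module
(default `ε = 0.1`); a pass may overshoot the window by one node
transiently, otherwise a tight window would freeze all moves, but only
in-window states can be accepted. No multilevel coarsening and no
hypergraph gain model are implemented: this is an open, reproducible
surrogate for hMetis-class partitioners, adequate for graphs of a few
thousand nodes, and exponents from hMetis itself are not expected to be
reproduced exactly. On finite lattices the coarse levels saturate (the
minimal halving cut of an `n × n` grid is one side length), so an
all-level fit sits well below the interior boundary/area exponent ½ —
the bisection analogue of Region II.

### Region segmentation

Given the empirical characteristic and an ensemble of characteristics
from degree-preserving randomizations:

- **Dispersion.** At each scale `b` represented with `P > 0` in at least
  two replicates, `c(b)` = sample standard deviation (ddof = 1) divided by
  mean of `{log₁₀ P̄ᵢ(b)}` over replicates `i`. Scales where that mean is
  not positive have no meaningful CV and are flagged. A plain
  (unlogged) CV is available behind a flag; the log form is the default
  because the bifurcation is multiplicative.
- **Region II** = all scales from the smallest `b*` with `c(b*) ≥ β`
  upward (default `β = 0.1`). Upward closure is deliberate: the
  bifurcation widens with `b`, and raw per-scale thresholding would let
  non-monotonic dips near `b_max` reopen Region I. Scales beyond the
  largest `b` at which the ensemble defines a dispersion are also
  Region II: there every replicate's covering has already collapsed
  (`P' = 0`), which is the extreme form of the bifurcation — randomized
  graphs have much smaller diameters than structured empirical ones, and
  without this rule the collapsing empirical tail would contaminate
  Region I whenever `c` never formally crosses `β` for lack of ensemble
  points.
- **Region III** (off by default): while the smallest-`B` remaining point
  lies above the fitted line (the rule *underestimates* it; the opposite
  sign convention is a flag) and dropping it raises `R²` by more than `ρ`
  (default `10⁻³`), move it to Region III and refit. The sequence of `R²`
  increments is reported. Trimming never proceeds past the point where
  fewer than three scales would remain.
- **Fits.** The Rent exponent is the OLS slope of `log₁₀ P` on `log₁₀ B`
  over Region I (slope standard error, `R²`, and the two-sided t-test
  p-value of the slope are reported; `k = 10^intercept`). Points with
  `P = 0` are kept in characteristics but always excluded from log fits.
  The sensitivity exponent `α` of `P' = K·P^α` is the OLS slope of the
  pooled per-replicate `log₁₀ P'` on the empirical `log₁₀ P` matched by
  scale, restricted to Region I for covering-based characteristics and
  typically unrestricted for bisection-based ones.

### Null models

Replicate `r` of model `m` is seeded by `crc32(f"{base_seed}:{m}:{r}") mod
2³¹`, so ensembles are reproducible and order-independent. Defaults follow
the reference analysis: 50 replicates, and for SA `20 × E` double-edge
swaps, counting *attempted* moves (a `successful` counting mode exists);
swaps that would create a self-loop or parallel edge are rejected, so the
degree sequence is preserved exactly. CM draws a configuration-model
multigraph on the empirical degree sequence and then collapses multi-edges
and loops — collapsing is preferred to rejection sampling, which would
bias toward low-multiedge graphs unless done carefully. CLM uses
`p_ij = min(1, d_i d_j / 2E)` (no self-loops). ER draws `G(N, E)`. CM,
CLM and ER keep their largest component; SA keeps all nodes (and may
rarely disconnect, which the covering handles per component, preserving
`N` and the per-module `P` semantics).

### Supporting statistics

Louvain modularity is seed-dependent, so `Q` is the best of 20 seeded runs
(networkx's Louvain implementation behind the package surface). `L` is
the BFS average shortest-path length over ordered pairs. Kendall's tau
uses tau-a with an exact one-sided p-value whenever the data are untied
and `n ≤ 12`: the null distribution of the discordant-pair count is the
inversion-number (Mahonian) distribution, computed by the standard
convolution recurrence in exact integer arithmetic and verified against
full permutation enumeration up to `n = 8`. Ties or larger `n` fall back
to tau-b with the tie-corrected normal approximation. Exact critical
values (`kendall_critical`) return the smallest tau whose tail probability
is ≤ α, and raise explicitly when no achievable level exists (at `n = 4`
the smallest one-sided level is `1/24`).

## Synthetic data

The fixture families span the regimes the analysis must handle: `grid2d` /
`grid3d` lattices (known scaling, `p ≈ ½` boundary/area in 2D), complete
binary `tree` and `ring` (low-exponent extremes), `hierarchical_modular`
(dense leaf modules of `s` nodes, `m`-way hierarchy of depth `ℓ`,
intra-module edge probability `q₁`, and probability `q₂^j` between nodes
whose deepest common ancestor is `j` levels up — coupling thinning
geometrically with hierarchical distance; stray components are linked
deterministically so small draws stay usable), and `geometric_random`
(unit-square geometric graph; seeds are retried until connected).
`synthetic_characteristic` draws `P = 10^(log₁₀ k + p·log₁₀ B + ε)` with
`ε ~ N(0, σ²)`: the exact generative model assumed by the fitting code,
hence its calibration oracle.

What the synthetic fixtures do *not* emulate: heavy-tailed degree
distributions of real interactomes, directed/weighted structure, and the
multi-thousand-node scales of the published analyses. Passing tests
demonstrate correctness of the machinery and calibration of the
estimators under the assumed model at desk scale, not the empirical
exponents of any particular real network — for those, the analysis
pipeline must be pointed at the downloaded datasets.

## Numerical choices and degenerate inputs

Node labels are opaque text; every internal index (distance matrices,
partition vectors) follows sorted label order, making runs reproducible
across platforms. Characteristic points are keyed by `B`; scales whose
mean module count collides are merged by averaging `P`, keeping `B`
strictly increasing. Fits require at least three positive-`P` points with
non-degenerate `B` and raise informative errors otherwise (segmentation
errors advise lowering `β`). `b = 1` coverings are always all singletons;
`b ≥ diameter + 1` is always a single box; the single-box point `(N, 0)`
is retained but never fitted. Preprocessing is idempotent and reports
what it removed. All analysis randomness descends from a single top-level
seed, and the pipeline's JSON report embeds the resolved configuration and
derived per-replicate seeds, so reruns are byte-identical.

## Problem sizes

The bundled analyses use lattices up to 32 × 32, a 128-node hierarchical
modular graph, ensembles of 10 replicates, 5 covering repetitions for
empirical curves and 1 for replicates, and FM with 4–10 restarts — sizes
chosen so the whole validation runs comfortably on one CPU while leaving
every scaling regime (Regions I and II, ensemble bifurcation, boundary
saturation) clearly visible. The same code drives larger networks
unchanged; the published multi-thousand-node analyses are minutes, not
hours, at 50 replicates.

## Known limitations

- Greedy covering's finite-size overhead biases fractal-dimension (not
  Rent-exponent) readings at small `N`, as quantified above.
- Flat FM is a surrogate for multilevel hypergraph partitioners; cut
  quality degrades on dense or very large graphs, and hypergraph-native
  pin counting is out of scope (nets are clique-expanded).
- Region II detection needs an ensemble that still resolves several
  scales; for very low-diameter graphs (complete-ish, `b_max ≤ 3`) there
  are too few scales for any meaningful fit, which the errors state.
- The exact Kendall machinery assumes untied data; ties always route to
  the approximate path regardless of `n`.
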
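"""Deterministic synthetic graphs and characteristics with known truth.

These families span the regimes the analysis must handle: lattices with
known fractal/Rentian scaling (a 2D grid has box-counting dimension 2
and bisection Rent exponent 1/2), trees and rings with tiny exponents,
hierarchical modular graphs mimicking the community structure of
connectomes and interactomes, and geometric random graphs.  A synthetic
Rent characteristic drawn directly from ``P = k B^p`` with log-normal
noise provides the ground-truth oracle for the fitting code.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .characteristic import RentCharacteristic, RentPoint

__all__ = ["make_benchmark_graph", "synthetic_characteristic", "FAMILIES"]

FAMILIES = ("grid2d", "grid3d", "tree", "ring", "hierarchical_modular", "geometric_random")


def _relabel(g: nx.Graph, name: str) -> nx.Graph:
    mapping = {v: str(v).replace(" ", "") for v in g.nodes}
    out = nx.relabel_nodes(nx.Graph(g), mapping)
    out.name = name
    return out


def _hierarchical_modular(
    levels: int, modules: int, module_size: int, p_intra: float, p_inter: float, seed: int
) -> nx.Graph:
    """Recursive modular graph: dense leaves, geometrically sparser glue.

    ``modules ** levels`` leaf modules of ``module_size`` nodes each.
    Within a leaf, edges appear with probability ``p_intra``; between
    nodes whose deepest common ancestor sits ℓ levels up, with
    probability ``p_inter ** ℓ`` — so coupling thins with hierarchical
    distance, the signature of hierarchical modular architectures.
    Connectivity is enforced afterwards by linking the first nodes of
    any stray components (deterministically), keeping the fixture
    usable at small sizes.
    """
    rng = np.random.default_rng(seed)
    n_leaves = modules**levels
    n = n_leaves * module_size
    g = nx.Graph()
    g.add_nodes_from(range(n))
    leaf_of = np.arange(n) // module_size
    for i in range(n):
        for j in range(i + 1, n):
            if leaf_of[i] == leaf_of[j]:
                p = p_intra
            else:
                # levels up to the deepest common ancestor of the two leaves
                a, b = leaf_of[i], leaf_of[j]
                ell = 0
                while a != b:
                    a //= modules
                    b //= modules
                    ell += 1
                p = p_inter**ell
            if rng.random() < p:
                g.add_edge(i, j)
    comps = sorted(nx.connected_components(g), key=lambda c: min(c))
    for prev, cur in zip(comps, comps[1:]):
        g.add_edge(min(prev), min(cur))
    return g


def make_benchmark_graph(family: str, seed: int = 0, **params) -> nx.Graph:
    """Build one synthetic benchmark graph.

    Parameters
    ----------
    family:
        ``grid2d(n)`` — n x n square lattice; ``grid3d(n)`` — n^3 cubic
        lattice; ``tree(depth)`` — complete binary tree; ``ring(n)`` —
        cycle; ``hierarchical_modular(levels, modules, module_size,
        p_intra, p_inter)``; ``geometric_random(n, radius)`` — random
        geometric graph in the unit square (seeds are retried until the
        draw is connected, falling back to the largest component).
    seed:
        Only the random families consume it; deterministic families
        ignore it, and every family is byte-reproducible for a fixed
        spec.
    """
    if family == "grid2d":
        n = int(params.get("n", 10))
        if n < 2:
            raise ValueError("grid2d needs n >= 2")
        return _relabel(nx.grid_2d_graph(n, n), f"grid2d-{n}")
    if family == "grid3d":
        n = int(params.get("n", 5))
        if n < 2:
            raise ValueError("grid3d needs n >= 2")
        return _relabel(nx.grid_graph(dim=(n, n, n)), f"grid3d-{n}")
    if family == "tree":
        depth = int(params.get("depth", 4))
        if depth < 1:
            raise ValueError("tree needs depth >= 1")
        return _relabel(nx.balanced_tree(2, depth), f"tree-{depth}")
    if family == "ring":
        n = int(params.get("n", 10))
        if n < 3:
            raise ValueError("ring needs n >= 3")
        return _relabel(nx.cycle_graph(n), f"ring-{n}")
    if family == "hierarchical_modular":
        levels = int(params.get("levels", 2))
        modules = int(params.get("modules", 4))
        module_size = int(params.get("module_size", 8))
        p_intra = float(params.get("p_intra", 0.6))
        p_inter = float(params.get("p_inter", 0.05))
        if min(levels, modules, module_size) < 1 or not (0 <= p_inter < p_intra <= 1):
            raise ValueError("invalid hierarchical_modular parameters")
        g = _hierarchical_modular(levels, modules, module_size, p_intra, p_inter, seed)
        return _relabel(g, f"hmod-{levels}x{modules}x{module_size}-s{seed}")
    if family == "geometric_random":
        n = int(params.get("n", 100))
        radius = float(params.get("radius", 0.15))
        if n < 2 or radius <= 0:
            raise ValueError("geometric_random needs n >= 2 and radius > 0")
        for attempt in range(50):
            g = nx.random_geometric_graph(n, radius, seed=seed + attempt)
            if nx.is_connected(g):
                break
        else:
            comp = max(nx.connected_components(g), key=len)
            g = g.subgraph(comp)
        return _relabel(g, f"geo-{n}-s{seed}")
    raise ValueError(f"unknown fixture family {family!r}; choose from {FAMILIES}")


def synthetic_characteristic(
    p: float,
    k: float,
    scales,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> RentCharacteristic:
    """Characteristic drawn exactly from Rent's rule plus log-normal noise.

    ``P = 10 ** (log10 k + p * log10 B + eps)`` with ``eps ~ N(0,
    noise_sigma^2)`` independently at each scale in ``scales``.  With
    ``noise_sigma = 0`` the points sit exactly on the power law, the
    oracle for noiseless recovery.
    """
    if p < 0 or k <= 0:
        raise ValueError("need exponent p >= 0 and coefficient k > 0")
    rng = np.random.default_rng(seed)
    points = []
    for i, B in enumerate(sorted(set(float(s) for s in scales))):
        eps = rng.normal(0.0, noise_sigma) if noise_sigma > 0 else 0.0
        P = 10 ** (np.log10(k) + p * np.log10(B) + eps)
        points.append(RentPoint(b=i + 1, B=B, P=float(P), n_modules=None))
    return RentCharacteristic(
        points=points,
        source="synthetic",
        meta={"true_p": p, "true_k": k, "noise_sigma": noise_sigma, "seed": seed},
    )
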
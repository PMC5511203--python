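"""Null-model ensembles for Rentian-scaling analysis.

Four random families, each matched to the empirical network in a
different way:

- **SA** — degree-preserving rewiring by double-edge swaps (the Markov
  chain scheme of Gkantsidis et al.); the degree sequence is exactly
  that of the input, and swaps that would create a self-loop or a
  parallel edge are rejected.
- **CM** — configuration model: uniform stub matching on the empirical
  degree sequence; the multigraph is then collapsed to a simple graph
  and the largest component kept.
- **CLM** — Chung–Lu expected-degree model: edge (i, j) present
  independently with probability min(1, d_i d_j / 2E); simple by
  construction, largest component kept.
- **ER** — Erdős–Rényi G(N, E) with the empirical order and size,
  largest component kept.

Replicates are seeded by a stated hash of ``(base_seed, model,
replicate)`` (CRC-32 of the formatted triple, reduced mod 2^31), so an
ensemble is reproducible and each replicate independent of how many
others are generated.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = ["RandomModelSpec", "replicate_seed", "generate_random", "generate_ensemble"]

MODELS = ("SA", "CM", "CLM", "ER")


@dataclass
class RandomModelSpec:
    """Which null model to draw, how hard to mix, and how many replicates."""

    model: str = "SA"
    swap_multiplier: int = 20
    sample_size: int = 50
    base_seed: int = 0

    def __post_init__(self) -> None:
        self.model = self.model.upper()
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.swap_multiplier < 1:
            raise ValueError("swap_multiplier must be >= 1")
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")


def replicate_seed(base_seed: int, model: str, replicate: int) -> int:
    """Deterministic per-replicate seed from (base seed, model tag, index)."""
    token = f"{base_seed}:{model.upper()}:{replicate}".encode()
    return zlib.crc32(token) % (2**31)


def _double_edge_swaps(
    g: nx.Graph, n_swaps: int, rng: np.random.Generator, count: str = "attempted"
) -> nx.Graph:
    """Apply double-edge swaps, preserving the degree sequence exactly.

    ``count`` decides whether ``n_swaps`` counts attempted moves
    (default; rejected moves still advance the counter) or successful
    ones.
    """
    h = g.copy()
    edges = list(h.edges())
    done = 0
    attempts = 0
    max_attempts = 100 * n_swaps + 1000
    while done < n_swaps and attempts < max_attempts:
        attempts += 1
        if count == "attempted":
            done = attempts
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        u, v = edges[i]
        x, y = edges[j]
        if rng.random() < 0.5:
            x, y = y, x
        # proposed rewiring: (u,v),(x,y) -> (u,x),(v,y)
        if u == x or v == y:
            continue
        if h.has_edge(u, x) or h.has_edge(v, y):
            continue
        h.remove_edge(u, v)
        h.remove_edge(x, y)
        h.add_edge(u, x)
        h.add_edge(v, y)
        edges[i] = (u, x)
        edges[j] = (v, y)
        if count == "successful":
            done += 1
    return h


def _largest_component(g: nx.Graph) -> nx.Graph:
    comp = max(nx.connected_components(g), key=lambda c: (len(c), min(map(str, c))))
    return nx.Graph(g.subgraph(comp))


def _cm_multigraph(degrees: list[int], seed: int) -> nx.MultiGraph:
    """Raw configuration-model draw (stub matching), before collapsing."""
    return nx.configuration_model(degrees, seed=seed)


def _clm_graph(degrees: list[int], seed: int) -> nx.Graph:
    """Chung-Lu draw: edge (i, j) with probability min(1, d_i d_j / 2E)."""
    return nx.expected_degree_graph(degrees, seed=seed, selfloops=False)


def generate_random(g: nx.Graph, spec: RandomModelSpec, replicate: int) -> nx.Graph:
    """Draw one replicate of the null model described by ``spec``.

    The input must be preprocessed (simple, connected).  SA replicates
    keep every node and the exact degree sequence but may disconnect;
    CM/CLM/ER replicates are reduced to their largest component.
    """
    if replicate >= spec.sample_size:
        raise ValueError("replicate index beyond sample_size")
    seed = replicate_seed(spec.base_seed, spec.model, replicate)
    rng = np.random.default_rng(seed)
    N, E = g.number_of_nodes(), g.number_of_edges()
    degrees = [d for _, d in sorted(g.degree, key=lambda kv: str(kv[0]))]

    if spec.model == "SA":
        out = _double_edge_swaps(g, spec.swap_multiplier * E, rng)
    elif spec.model == "CM":
        mg = _cm_multigraph(degrees, seed=int(rng.integers(2**31)))
        simple = nx.Graph(mg)  # collapses parallel edges
        simple.remove_edges_from(nx.selfloop_edges(simple))
        out = _largest_component(simple)
    elif spec.model == "CLM":
        out = _largest_component(_clm_graph(degrees, seed=int(rng.integers(2**31))))
    elif spec.model == "ER":
        if E > N * (N - 1) // 2:
            raise ValueError("E exceeds the maximum for a simple graph on N nodes")
        out = _largest_component(nx.gnm_random_graph(N, E, seed=int(rng.integers(2**31))))
    else:  # pragma: no cover - guarded by RandomModelSpec
        raise ValueError(spec.model)
    out.graph["model"] = spec.model
    out.graph["replicate"] = replicate
    out.graph["seed"] = seed
    return out


def generate_ensemble(g: nx.Graph, spec: RandomModelSpec) -> list[nx.Graph]:
    """The full replicate sample (``spec.sample_size`` graphs)."""
    return [generate_random(g, spec, r) for r in range(spec.sample_size)]
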
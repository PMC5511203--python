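"""Greedy box covering of a graph at every scale.

A *box* of size ``b`` is a set of nodes whose pairwise shortest-path
distance in the host graph is at most ``b - 1``.  Partitioning the graph
into as few boxes as possible is the box-counting construction used to
measure the fractal dimension of a network, and here it supplies the
hierarchy of topological partitions behind the Rent characteristic.

The covering uses the greedy-coloring formulation: nodes are visited in
a random order and each node receives the smallest color not already
held by a node at distance ``>= b``; color classes are the boxes.  A box
so built constrains pairwise distance only — it may induce a
disconnected subgraph, which is the standard behaviour of the coloring
formulation.  Minimal covering is NP-hard; greedy coloring is a cheap
approximation whose dispersion across visit orders is small.

Distances are exact shortest paths computed once per graph (SciPy BFS)
and reused for every scale, and a single visit order is reused across
all scales of one covering sequence, so one seed yields one coherent
hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

from .graph import node_order

__all__ = ["BoxCovering", "distance_matrix", "greedy_box_covering", "covering_sequence"]


@dataclass
class BoxCovering:
    """A partition of the node set into boxes of diameter ``<= box_size - 1``."""

    box_size: int
    boxes: list[set]
    seed: int

    @property
    def n_boxes(self) -> int:
        return len(self.boxes)


def distance_matrix(g: nx.Graph) -> tuple[np.ndarray, list]:
    """All-pairs shortest-path distances, nodes in sorted-label order.

    Returns the dense distance matrix (``inf`` across components) and the
    node list indexing it.
    """
    nodes = node_order(g)
    adj = nx.to_scipy_sparse_array(g, nodelist=nodes, format="csr")
    dist = shortest_path(adj, method="D", unweighted=True, directed=False)
    return dist, nodes


def _color_order(dist: np.ndarray, order: np.ndarray, b: int) -> np.ndarray:
    """Greedy coloring: node i may share a color only with nodes at distance < b."""
    n = len(order)
    colors = np.empty(n, dtype=np.int64)  # colors[i] = color of order[i]
    dist_ord = dist[np.ix_(order, order)]
    for i in range(n):
        if i == 0:
            colors[0] = 0
            continue
        conflicting = colors[:i][dist_ord[i, :i] >= b]
        if conflicting.size == 0:
            colors[i] = 0
            continue
        forbidden = set(conflicting.tolist())
        c = 0
        while c in forbidden:
            c += 1
        colors[i] = c
    return colors


def greedy_box_covering(
    g: nx.Graph,
    b: int,
    seed: int,
    *,
    _dist: np.ndarray | None = None,
    _nodes: list | None = None,
    _order: np.ndarray | None = None,
) -> BoxCovering:
    """Cover ``g`` with boxes of size ``b`` using one random visit order.

    Parameters
    ----------
    g:
        Host graph (connected unless called through the internal
        multi-component path).
    b:
        Box size; boxes have diameter at most ``b - 1`` in ``g``.
    seed:
        Determines the visit order.

    The keyword-only arguments let :func:`covering_sequence` reuse the
    distance matrix and the permutation across scales.
    """
    if b < 1:
        raise ValueError(f"box size must be >= 1, got {b}")
    if _dist is None or _nodes is None:
        _dist, _nodes = distance_matrix(g)
    n = len(_nodes)
    if _order is None:
        _order = np.random.default_rng(seed).permutation(n)
    colors = _color_order(_dist, _order, b)
    boxes: dict[int, set] = {}
    for pos, c in enumerate(colors):
        boxes.setdefault(int(c), set()).add(_nodes[_order[pos]])
    return BoxCovering(box_size=b, boxes=[boxes[c] for c in sorted(boxes)], seed=seed)


def covering_sequence(
    g: nx.Graph, seed: int, allow_disconnected: bool = False
) -> list[BoxCovering]:
    """Box coverings for every scale ``b = 1 .. b_max``.

    ``b_max`` is the first box size at which the covering collapses to a
    single box, i.e. the graph diameter plus one.  One node permutation,
    drawn from ``seed``, is shared by all scales.

    For disconnected graphs (``allow_disconnected=True``, used when
    analysing degree-preserving randomizations that happen to split the
    graph) boxes never span components — cross-component distance is
    infinite, hence always ``>= b`` — and ``b_max`` is the largest
    component diameter plus one, where the covering collapses to one box
    per component.
    """
    if not allow_disconnected and not nx.is_connected(g):
        raise ValueError(
            "graph is disconnected; run rentian.graph.preprocess first to "
            "keep the largest connected component"
        )
    dist, nodes = distance_matrix(g)
    finite = dist[np.isfinite(dist)]
    diameter = int(finite.max()) if finite.size else 0
    order = np.random.default_rng(seed).permutation(len(nodes))
    out = []
    for b in range(1, diameter + 2):
        out.append(
            greedy_box_covering(g, b, seed, _dist=dist, _nodes=nodes, _order=order)
        )
    return out
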
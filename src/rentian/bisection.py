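"""Recursive balanced graph bisection with Fiduccia–Mattheyses refinement.

The classical route to a Rent characteristic: split the network into
two nearly equal halves minimizing the number of cut edges, then split
each half again, and so on.  Each recursion level is one partition of
the node set; level ℓ has at most 2^ℓ modules and supplies one point of
the characteristic.

Each split draws several random balanced starting bisections and
refines each with FM passes — single-node moves ordered by cut gain
through an integer bucket structure, with moved nodes locked for the
rest of the pass and the best prefix of moves kept — taking the best of
the restarts.  This is an ordinary flat min-cut bisection (no
multilevel coarsening or hypergraph handling), adequate for extracting
partition hierarchies from graphs of a few thousand nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .characteristic import RentCharacteristic, compute_characteristic
from .graph import node_order

__all__ = ["BisectionTree", "fm_bisect", "recursive_bisect", "bisect_characteristic"]


@dataclass
class BisectionTree:
    """Partition hierarchy produced by recursive bisection.

    ``levels[ℓ]`` is a partition of the full node set into at most 2^ℓ
    modules; level 0 is the whole graph.
    """

    levels: list[list[set]]
    balance_tolerance: float
    restarts: int
    seed: int


def _cut_size(adj: dict, side: dict) -> int:
    cut = 0
    for u, nbrs in adj.items():
        su = side[u]
        for v in nbrs:
            if side[v] != su:
                cut += 1
    return cut // 2


def fm_bisect(
    g: nx.Graph,
    nodes: list,
    epsilon: float,
    restarts: int,
    rng: np.random.Generator,
) -> tuple[set, set, int]:
    """Best-of-restarts FM bisection of ``nodes`` within ``g``.

    Only edges internal to ``nodes`` count.  Side sizes are constrained
    to within ``epsilon`` of a perfect half (each side holds between
    ``ceil(n(1/2 - epsilon))`` and ``floor(n(1/2 + epsilon))`` nodes,
    never empty).  Returns the two sides and the cut size.
    """
    n = len(nodes)
    if n < 2:
        raise ValueError("cannot bisect fewer than two nodes")
    node_set = set(nodes)
    adj = {u: [v for v in g.neighbors(u) if v in node_set] for u in nodes}
    lo = max(1, min(int(np.ceil(n * (0.5 - epsilon))), n // 2))
    hi = min(n - 1, max(int(np.floor(n * (0.5 + epsilon))), (n + 1) // 2))
    half = n // 2

    best_side: dict | None = None
    best_cut = None
    for _ in range(max(1, restarts)):
        perm = list(nodes)
        rng.shuffle(perm)
        side = {u: (0 if i < half else 1) for i, u in enumerate(perm)}
        cut = _cut_size(adj, side)
        improved = True
        while improved:
            improved = False
            cut_new, side_new = _fm_pass(adj, nodes, side, cut, lo, hi)
            if cut_new < cut:
                cut, side = cut_new, side_new
                improved = True
        if best_cut is None or cut < best_cut:
            best_cut, best_side = cut, side
    a = {u for u in nodes if best_side[u] == 0}
    b = {u for u in nodes if best_side[u] == 1}
    return a, b, int(best_cut)


def _fm_pass(
    adj: dict, nodes: list, side: dict, cut: int, lo: int, hi: int
) -> tuple[int, dict]:
    """One FM pass: move every node once, keep the best feasible prefix.

    Moves may leave the balance window by one node transiently (otherwise
    a tight window freezes the pass); only prefixes whose sizes are back
    inside ``[lo, hi]`` are eligible as the best state.
    """
    n_total = len(nodes)
    explore_lo = max(1, lo - 1)
    explore_hi = min(n_total - 1, hi + 1)
    side = dict(side)
    sizes = [0, 0]
    for u in nodes:
        sizes[side[u]] += 1
    # gain(u) = external - internal edges; moving u changes cut by -gain
    gains = {}
    for u in nodes:
        ext = sum(1 for v in adj[u] if side[v] != side[u])
        gains[u] = 2 * ext - len(adj[u])

    max_deg = max((len(adj[u]) for u in nodes), default=0)
    buckets: list[set] = [set() for _ in range(2 * max_deg + 1)]
    offset = max_deg
    for u in nodes:
        buckets[gains[u] + offset].add(u)
    bucket_top = 2 * max_deg

    locked: set = set()
    order: list = []
    cur = cut
    best = cut
    best_prefix = 0
    for step in range(len(nodes)):
        # highest-gain unlocked node whose move keeps both sides in range
        chosen = None
        for gi in range(bucket_top, -1, -1):
            for u in buckets[gi]:
                s = side[u]
                if sizes[s] - 1 >= explore_lo and sizes[1 - s] + 1 <= explore_hi:
                    chosen = u
                    break
            if chosen is not None:
                break
        if chosen is None:
            break
        u = chosen
        buckets[gains[u] + offset].discard(u)
        locked.add(u)
        s = side[u]
        sizes[s] -= 1
        sizes[1 - s] += 1
        cur -= gains[u]
        side[u] = 1 - s
        order.append(u)
        for v in adj[u]:
            if v in locked:
                continue
            old = gains[v]
            # u switched sides; if the (u,v) edge is external now it was
            # internal before, so v's gain rises by 2 (and vice versa)
            gains[v] = old + (2 if side[u] != side[v] else -2)
            buckets[old + offset].discard(v)
            buckets[gains[v] + offset].add(v)
        if cur < best and lo <= sizes[0] <= hi:
            best = cur
            best_prefix = len(order)

    # roll back moves beyond the best prefix
    for u in order[best_prefix:]:
        side[u] = 1 - side[u]
    return best, side


def recursive_bisect(
    g: nx.Graph,
    max_depth: int | None = None,
    epsilon: float = 0.1,
    restarts: int = 10,
    seed: int = 0,
) -> BisectionTree:
    """Build the full partition hierarchy of a graph.

    Splits every module of two or more nodes at each level, stopping at
    ``max_depth`` levels below the root (default: recurse until all
    modules are singletons).
    """
    if not (0 < epsilon < 0.5):
        raise ValueError(f"epsilon must be in (0, 0.5), got {epsilon}")
    rng = np.random.default_rng(seed)
    ordered = node_order(g)
    levels: list[list[set]] = [[set(ordered)]]
    depth = 0
    while max_depth is None or depth < max_depth:
        current = levels[-1]
        if all(len(m) <= 1 for m in current):
            break
        nxt: list[set] = []
        for module in current:
            if len(module) <= 1:
                nxt.append(set(module))
                continue
            mod_nodes = sorted(module, key=str)
            a, b, _ = fm_bisect(g, mod_nodes, epsilon, restarts, rng)
            nxt.extend([a, b])
        levels.append(nxt)
        depth += 1
    return BisectionTree(levels=levels, balance_tolerance=epsilon, restarts=restarts, seed=seed)


def bisect_characteristic(g: nx.Graph, tree: BisectionTree) -> RentCharacteristic:
    """Rent characteristic from the levels of a bisection tree.

    The scale label of level ℓ counts up from the deepest level, so
    larger ``b`` means larger modules, as with box sizes.
    """
    depth = len(tree.levels)
    char = compute_characteristic(
        g,
        partitions=list(tree.levels),
        b_values=[depth - ell for ell in range(depth)],
        source="bipartition",
    )
    char.meta.update(
        {"epsilon": tree.balance_tolerance, "restarts": tree.restarts, "seed": tree.seed}
    )
    return char
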
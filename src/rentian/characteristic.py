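"""The empirical Rent characteristic P_c(B) of a partition hierarchy.

For a partition of a network into modules, ``B`` is the average number
of nodes per module (``N`` divided by the module count) and ``P`` is the
average number of external edges per module, where every cut edge
contributes one external connection to *each* of its two incident
modules — the graph analogue of counting pins on a module.  A family of
partitions (box coverings across scales, or the levels of a recursive
bisection) then traces the discrete curve ``P = P_c(B)`` whose power-law
range is Rent's rule ``P = k B^p``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .covering import BoxCovering, covering_sequence

__all__ = [
    "RentPoint",
    "RentCharacteristic",
    "external_edge_counts",
    "compute_characteristic",
    "covering_characteristic",
]


@dataclass(frozen=True)
class RentPoint:
    """One point of a Rent characteristic.

    ``b`` is the partition scale (box size, or bisection level counted
    from the leaves); ``n_modules`` may be fractional when the point
    averages several random coverings at the same scale.
    """

    b: int | None
    B: float
    P: float
    n_modules: float | None = None


@dataclass
class RentCharacteristic:
    """Sequence of (B, P) points ordered by increasing B."""

    points: list[RentPoint]
    source: str = "box_covering"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = sorted(self.points, key=lambda pt: pt.B)
        Bs = [pt.B for pt in self.points]
        if any(b2 <= b1 for b1, b2 in zip(Bs, Bs[1:])):
            raise ValueError("B values must be strictly increasing")
        if self.points and self.points[0].B < 1:
            raise ValueError("smallest module size B must be >= 1")

    def positive(self) -> list[RentPoint]:
        """Points usable in a log-log fit (``P > 0``)."""
        return [pt for pt in self.points if pt.P > 0]

    def point_at(self, b: int) -> RentPoint | None:
        for pt in self.points:
            if pt.b == b:
                return pt
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "b": [pt.b for pt in self.points],
                "n_modules": [pt.n_modules for pt in self.points],
                "B": [pt.B for pt in self.points],
                "P": [pt.P for pt in self.points],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_json(self, path: str | Path) -> None:
        payload = {
            "source": self.source,
            "meta": self.meta,
            "points": [
                {"b": pt.b, "n_modules": pt.n_modules, "B": pt.B, "P": pt.P}
                for pt in self.points
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def external_edge_counts(g: nx.Graph, partition: list[set]) -> list[int]:
    """External-edge (pin) count of every module of a partition.

    Each cut edge is counted once for each of its two incident modules,
    so the counts sum to twice the number of cut edges.

    Raises
    ------
    ValueError
        If the modules do not cover every node exactly once.
    """
    owner: dict = {}
    for mid, module in enumerate(partition):
        for v in module:
            if v in owner:
                raise ValueError(f"node {v!r} appears in more than one module")
            owner[v] = mid
    if len(owner) != g.number_of_nodes() or any(v not in owner for v in g.nodes):
        raise ValueError("partition does not cover all nodes of the graph")
    ext = [0] * len(partition)
    for u, v in g.edges():
        mu, mv = owner[u], owner[v]
        if mu != mv:
            ext[mu] += 1
            ext[mv] += 1
    return ext


def compute_characteristic(
    g: nx.Graph,
    partitions: list[list[set]],
    b_values: list[int] | None = None,
    source: str = "box_covering",
) -> RentCharacteristic:
    """Turn a hierarchy of partitions into a Rent characteristic.

    Parameters
    ----------
    g:
        The partitioned network.
    partitions:
        One partition (list of node sets) per scale.  Partitions whose
        mean module size B collides with an earlier partition's are
        merged by averaging P (distinct scales can produce the same
        module count).
    b_values:
        Optional scale labels, one per partition.
    """
    N = g.number_of_nodes()
    by_B: dict[float, list[tuple[int | None, float, float]]] = {}
    for idx, partition in enumerate(partitions):
        ext = external_edge_counts(g, partition)
        n_mod = len(partition)
        B = N / n_mod
        P = sum(ext) / n_mod
        b = b_values[idx] if b_values is not None else None
        by_B.setdefault(B, []).append((b, P, float(n_mod)))
    points = []
    for B, entries in by_B.items():
        b = entries[0][0]
        P = float(np.mean([e[1] for e in entries]))
        n_mod = entries[0][2]
        points.append(RentPoint(b=b, B=B, P=P, n_modules=n_mod))
    return RentCharacteristic(points=points, source=source, meta={"N": N, "E": g.number_of_edges()})


def covering_characteristic(
    g: nx.Graph,
    seed: int,
    repetitions: int = 10,
    allow_disconnected: bool = False,
) -> RentCharacteristic:
    """Rent characteristic of a graph from greedy box coverings.

    Runs ``repetitions`` independent covering sequences (one random
    visit order each, seeded ``seed, seed+1, ...``) and averages the
    per-scale module count and external-connection count: at each box
    size ``b``, ``B = N / mean(n_boxes)`` and ``P`` is the mean over
    repetitions of the per-covering average external edges per box.
    Random choices in the greedy coloring perturb individual coverings
    only mildly, so a handful of repetitions stabilises the curve.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    N = g.number_of_nodes()
    acc: dict[int, list[tuple[int, float]]] = {}
    for rep in range(repetitions):
        seq = covering_sequence(g, seed + rep, allow_disconnected=allow_disconnected)
        for cov in seq:
            ext = external_edge_counts(g, cov.boxes)
            acc.setdefault(cov.box_size, []).append(
                (cov.n_boxes, sum(ext) / cov.n_boxes)
            )
    points = []
    seen_B: set[float] = set()
    for b in sorted(acc):
        entries = acc[b]
        mean_boxes = float(np.mean([n for n, _ in entries]))
        B = N / mean_boxes
        P = float(np.mean([p for _, p in entries]))
        if B in seen_B:  # same module count at consecutive scales
            continue
        seen_B.add(B)
        points.append(RentPoint(b=b, B=B, P=P, n_modules=mean_boxes))
    # collisions after averaging are rare but must keep B strictly increasing
    points = _dedupe_monotone(points)
    return RentCharacteristic(
        points=points,
        source="box_covering",
        meta={"N": N, "E": g.number_of_edges(), "seed": seed, "repetitions": repetitions},
    )


def _dedupe_monotone(points: list[RentPoint]) -> list[RentPoint]:
    points = sorted(points, key=lambda pt: (pt.B, pt.b if pt.b is not None else 0))
    out: list[RentPoint] = []
    for pt in points:
        if out and pt.B <= out[-1].B:
            prev = out.pop()
            merged = RentPoint(
                b=prev.b,
                B=prev.B,
                P=(prev.P + pt.P) / 2,
                n_modules=prev.n_modules,
            )
            out.append(merged)
        else:
            out.append(pt)
    return out
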
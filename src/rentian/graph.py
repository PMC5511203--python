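"""Network and netlist input, hypergraph expansion, and preprocessing.

Networks arrive as plain edge lists, GML or Pajek files; VLSI circuits
arrive as hypergraph netlists (ISCAS89 ``.bench``-style or ISPD98
``.net``-style) and are converted to ordinary graphs by clique expansion.
All downstream analysis assumes a simple, undirected, connected graph:
:func:`preprocess` drops edge direction, removes self-loops, collapses
parallel edges and keeps only the largest connected component, reporting
how much was removed at each step.

Node labels are opaque text throughout; whenever a contiguous integer
index is needed (distance matrices, partition vectors) it is assigned by
sorted label order so results are reproducible across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "HyperNetlist",
    "ParseError",
    "load_graph",
    "load_netlist",
    "expand_hypergraph",
    "preprocess",
    "node_order",
    "write_edgelist",
]


class ParseError(ValueError):
    """A file could not be interpreted in the requested dialect."""


@dataclass
class HyperNetlist:
    """A hypergraph netlist: cells connected by multi-terminal nets.

    Nets with fewer than two distinct cells carry no connectivity and are
    removed on construction (the number dropped is logged).
    """

    cells: set[str]
    nets: list[frozenset[str]]
    name: str = ""

    def __post_init__(self) -> None:
        kept = []
        dropped = 0
        for net in self.nets:
            net = frozenset(net)
            if len(net) >= 2:
                kept.append(net)
            else:
                dropped += 1
        if dropped:
            logger.info("dropped %d nets of size < 2", dropped)
        self.nets = kept
        missing = set().union(*self.nets) - self.cells if self.nets else set()
        if missing:
            raise ValueError(f"nets reference unknown cells: {sorted(missing)[:5]}")


def node_order(g: nx.Graph) -> list:
    """Deterministic node ordering: sorted by string form of the label."""
    return sorted(g.nodes, key=str)


def load_graph(path: str | Path, format: str = "edgelist") -> nx.MultiGraph:
    """Read a network file, keeping any self-loops and parallel edges.

    Parameters
    ----------
    path:
        File to read.
    format:
        One of ``edgelist`` (whitespace-delimited pairs, ``#`` comments),
        ``gml`` or ``pajek``.

    Returns
    -------
    networkx.MultiGraph
        The graph exactly as stored; duplicated edge lines appear as
        parallel edges so that :func:`preprocess` can report them.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"cannot read graph file: {path}")
    if format == "edgelist":
        g = nx.MultiGraph(name=path.stem)
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) < 2:
                    raise ParseError(f"{path}:{lineno}: expected two node labels, got {line!r}")
                u, v = parts[0], parts[1]
                g.add_edge(u, v)
        if g.number_of_nodes() == 0:
            logger.warning("empty graph read from %s", path)
        return g
    if format == "gml":
        try:
            g = nx.read_gml(path, label="label")
        except Exception as exc:  # networkx raises its own parser errors
            raise ParseError(f"{path}: not valid GML: {exc}") from exc
        return nx.MultiGraph(g, name=path.stem)
    if format == "pajek":
        try:
            g = nx.read_pajek(path)
        except Exception as exc:
            raise ParseError(f"{path}: not valid Pajek: {exc}") from exc
        return nx.MultiGraph(g, name=path.stem)
    raise ValueError(f"unknown graph format: {format!r}")


def _parse_bench(path: Path) -> HyperNetlist:
    # ISCAS89 .bench dialect: INPUT(x) / OUTPUT(x) / y = FUNC(a, b, ...).
    # Cells are primary inputs and gates (each gate named by its output
    # signal).  Each signal defines a net joining its driver to every gate
    # that reads it.
    cells: set[str] = set()
    fanin: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("INPUT(") and line.endswith(")"):
                cells.add(line[line.index("(") + 1 : -1].strip())
            elif upper.startswith("OUTPUT(") and line.endswith(")"):
                continue  # output markers add no connectivity
            elif "=" in line:
                lhs, rhs = (s.strip() for s in line.split("=", 1))
                if "(" not in rhs or not rhs.endswith(")"):
                    raise ParseError(f"{path}:{lineno}: malformed gate definition {raw.strip()!r}")
                args = rhs[rhs.index("(") + 1 : -1]
                srcs = [a.strip() for a in args.split(",") if a.strip()]
                cells.add(lhs)
                fanin[lhs] = srcs
            else:
                raise ParseError(f"{path}:{lineno}: unknown directive {raw.strip()!r}")
    # net for signal s: {s} ∪ {gates reading s}
    readers: dict[str, set[str]] = {}
    for gate, srcs in fanin.items():
        for s in srcs:
            readers.setdefault(s, set()).add(gate)
    nets = []
    for signal, sinks in readers.items():
        if signal not in cells:
            raise ParseError(f"{path}: signal {signal!r} used but never defined")
        nets.append(frozenset({signal} | sinks))
    return HyperNetlist(cells=cells, nets=nets, name=path.stem)


def _parse_ispd98(path: Path) -> HyperNetlist:
    # Minimal ISPD98 .net dialect: optional leading integer header lines,
    # then one cell name per line followed by 's' (starts a net) or 'l'
    # (continues the current net).
    cells: set[str] = set()
    nets: list[set[str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) == 1 and parts[0].isdigit():
                continue  # header counts; sizes are re-derived from content
            if len(parts) < 2 or parts[1] not in ("s", "l"):
                raise ParseError(f"{path}:{lineno}: unknown directive {raw.strip()!r}")
            cell, marker = parts[0], parts[1]
            cells.add(cell)
            if marker == "s":
                nets.append({cell})
            else:
                if not nets:
                    raise ParseError(f"{path}:{lineno}: continuation before any net start")
                nets[-1].add(cell)
    return HyperNetlist(cells=cells, nets=[frozenset(n) for n in nets], name=path.stem)


def load_netlist(path: str | Path, dialect: str = "iscas89") -> HyperNetlist:
    """Read a VLSI netlist as a hypergraph (cells + nets).

    Only connectivity is retained: timing and area fields are ignored.
    ``dialect`` is ``iscas89`` (``.bench`` style) or ``ispd98``
    (``.net`` style).
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"cannot read netlist file: {path}")
    if dialect == "iscas89":
        return _parse_bench(path)
    if dialect == "ispd98":
        return _parse_ispd98(path)
    raise ValueError(f"unknown netlist dialect: {dialect!r}")


def expand_hypergraph(h: HyperNetlist) -> nx.Graph:
    """Clique-expand a hypergraph into a simple graph.

    Every pair of cells sharing a net becomes an edge; repeated pairs
    collapse to one edge.  Clique expansion keeps the node set identical
    to the cell set, so the order N and the degree sequence refer to the
    physical cells (a star expansion would add artificial net nodes).
    """
    g = nx.Graph(name=h.name)
    g.add_nodes_from(h.cells)
    for net in h.nets:
        g.add_edges_from(combinations(sorted(net), 2))
    return g


def preprocess(g: nx.Graph, directed_input: bool = False) -> nx.Graph:
    """Reduce any loaded graph to the simple undirected analysis form.

    Direction is dropped (a unidirectional connection becomes a single
    undirected edge), self-loops are removed, parallel edges are
    collapsed, and only the largest connected component is kept.  Counts
    of removed loops, collapsed multi-edges and discarded nodes/edges are
    stored in ``result.graph["preprocess"]`` and logged.

    Raises
    ------
    ValueError
        If nothing remains after filtering.
    """
    name = g.name if isinstance(g.name, str) else ""
    if directed_input or g.is_directed():
        g = g.to_undirected()

    simple = nx.Graph(name=name)
    simple.add_nodes_from(g.nodes)
    loops = 0
    multiplicity = 0
    seen: set[frozenset] = set()
    for u, v in g.edges():
        if u == v:
            loops += 1
            continue
        key = frozenset((u, v))
        if key in seen:
            multiplicity += 1
            continue
        seen.add(key)
        simple.add_edge(u, v)

    if simple.number_of_nodes() == 0:
        raise ValueError("graph is empty after preprocessing")
    components = sorted(nx.connected_components(simple), key=lambda c: (-len(c), min(map(str, c))))
    largest = components[0]
    removed_nodes = simple.number_of_nodes() - len(largest)
    out = nx.Graph(simple.subgraph(largest), name=name)
    if out.number_of_edges() == 0 and out.number_of_nodes() <= 1 and (loops or multiplicity or removed_nodes):
        # a lone node surviving a filtered-out graph is not analysable
        if simple.number_of_edges() == 0:
            raise ValueError("graph has no edges after preprocessing")
    out.graph["preprocess"] = {
        "self_loops_removed": loops,
        "parallel_edges_collapsed": multiplicity,
        "nodes_outside_largest_component": removed_nodes,
        "components": len(components),
    }
    logger.info(
        "preprocess(%s): removed %d loops, collapsed %d parallel edges, "
        "dropped %d nodes outside largest component",
        name or "<unnamed>", loops, multiplicity, removed_nodes,
    )
    return out


def write_edgelist(g: nx.Graph, path: str | Path) -> None:
    """Write a canonical edge list: each edge once, endpoints and lines sorted."""
    lines = sorted(
        "{} {}".format(*sorted((str(u), str(v)))) for u, v in g.edges()
    )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
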
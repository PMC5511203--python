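"""From a VLSI netlist to an analysable graph.

Circuits are hypergraphs (a net can touch many cells); clique expansion
turns each net into a clique over its cells so the whole Rentian
toolchain applies unchanged.
"""

import tempfile
from pathlib import Path

import rentian as rt

bench = """\
# toy ISCAS89-style circuit
INPUT(a)
INPUT(b)
OUTPUT(out)
n1 = NAND(a, b)
n2 = NOT(n1)
n3 = NOR(n1, b)
out = AND(n2, n3)
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "toy.bench"
    path.write_text(bench)
    netlist = rt.load_netlist(path, dialect="iscas89")
    print(f"cells: {sorted(netlist.cells)}")
    print(f"nets:  {[sorted(net) for net in netlist.nets]}")

    g = rt.preprocess(rt.expand_hypergraph(netlist))
    print(f"clique-expanded graph: N = {g.number_of_nodes()}, E = {g.number_of_edges()}")
    char = rt.covering_characteristic(g, seed=0, repetitions=3)
    print("Rent characteristic (B, P):",
          [(round(pt.B, 2), round(pt.P, 2)) for pt in char.points])
# Each signal becomes a net over its driver and readers; a net of k cells
# contributes up to k(k-1)/2 edges, deduplicated across nets.
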
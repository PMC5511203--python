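import networkx as nx
import pytest

from rentian import make_benchmark_graph


@pytest.fixture
def path4() -> nx.Graph:
    g = nx.path_graph(4)
    return nx.relabel_nodes(g, {i: "abcd"[i] for i in range(4)})


@pytest.fixture
def grid5() -> nx.Graph:
    return make_benchmark_graph("grid2d", n=5)


@pytest.fixture
def small_fixture_zoo() -> list[nx.Graph]:
    """Connected graphs of <= 50 nodes spanning all fixture families."""
    return [
        make_benchmark_graph("grid2d", n=4),
        make_benchmark_graph("grid3d", n=3),
        make_benchmark_graph("tree", depth=3),
        make_benchmark_graph("ring", n=12),
        make_benchmark_graph("hierarchical_modular", levels=1, modules=4,
                             module_size=6, p_intra=0.7, p_inter=0.15, seed=2),
        make_benchmark_graph("geometric_random", n=40, radius=0.3, seed=5),
    ]


def write_lines(path, text):
    path.write_text(text)
    return str(path)
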
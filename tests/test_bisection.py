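"""Recursive FM bisection: cut quality, balance, and the grid exponent."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from rentian import (
    bisect_characteristic,
    fit_rent,
    fm_bisect,
    make_benchmark_graph,
    recursive_bisect,
)


def exhaustive_min_balanced_cut(g):
    """Minimum cut over all floor(n/2)-element bisections (oracle)."""
    nodes = list(g.nodes)
    n = len(nodes)
    best = None
    for side_a in combinations(nodes, n // 2):
        a = set(side_a)
        cut = sum(1 for u, v in g.edges() if (u in a) != (v in a))
        best = cut if best is None else min(best, cut)
    return best


class TestFmBisect:
    def test_path_split_matches_exhaustive_minimum(self, path4):
        a, b, cut = fm_bisect(path4, list(path4.nodes), epsilon=0.1, restarts=5,
                              rng=np.random.default_rng(0))
        assert cut == exhaustive_min_balanced_cut(path4) == 1
        assert {frozenset(a), frozenset(b)} == {frozenset("ab"), frozenset("cd")}

    def test_k4_any_balanced_split_cuts_four(self):
        g = nx.complete_graph(4)
        _, _, cut = fm_bisect(g, list(g.nodes), epsilon=0.1, restarts=3,
                              rng=np.random.default_rng(1))
        assert cut == exhaustive_min_balanced_cut(g) == 4

    @pytest.mark.parametrize("seed", range(5))
    def test_fm_matches_exhaustive_on_random_graphs(self, seed):
        g = nx.gnp_random_graph(10, 0.4, seed=seed)
        if not nx.is_connected(g):
            g = nx.Graph(g.subgraph(max(nx.connected_components(g), key=len)))
        a, b, cut = fm_bisect(g, list(g.nodes), epsilon=0.05, restarts=10,
                              rng=np.random.default_rng(seed))
        assert cut == exhaustive_min_balanced_cut(g)

    def test_never_worse_than_best_random_start(self):
        """FM refinement cannot lose to the raw random bisections it refines."""
        g = make_benchmark_graph("hierarchical_modular", levels=1, modules=2,
                                 module_size=10, p_intra=0.6, p_inter=0.05, seed=0)
        nodes = sorted(g.nodes, key=str)
        n = len(nodes)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            _, _, fm_cut = fm_bisect(g, nodes, epsilon=0.1, restarts=3, rng=rng)
            rng2 = np.random.default_rng(seed + 1000)
            random_cuts = []
            for _ in range(3):
                perm = list(nodes)
                rng2.shuffle(perm)
                a = set(perm[: n // 2])
                random_cuts.append(sum(1 for u, v in g.edges() if (u in a) != (v in a)))
            assert fm_cut <= min(random_cuts)

    def test_balance_respected(self):
        g = make_benchmark_graph("grid2d", n=6)
        nodes = sorted(g.nodes, key=str)
        a, b, _ = fm_bisect(g, nodes, epsilon=0.1, restarts=2, rng=np.random.default_rng(3))
        n = len(nodes)
        assert max(1, int(np.ceil(n * 0.4))) <= len(a) <= int(np.floor(n * 0.6))
        assert a | b == set(nodes) and not (a & b)


class TestRecursiveBisect:
    def test_levels_partition_and_halve(self, grid5):
        tree = recursive_bisect(grid5, max_depth=3, epsilon=0.1, restarts=3, seed=2)
        N = grid5.number_of_nodes()
        for ell, level in enumerate(tree.levels):
            assert len(level) <= 2**ell
            covered = set().union(*level)
            assert covered == set(grid5.nodes)
            assert sum(len(m) for m in level) == N

    def test_single_node_graph(self):
        g = nx.Graph()
        g.add_node("v")
        tree = recursive_bisect(g, seed=0)
        assert tree.levels == [[{"v"}]]

    def test_epsilon_out_of_range(self, grid5):
        with pytest.raises(ValueError, match="epsilon"):
            recursive_bisect(grid5, epsilon=0.7)

    def test_full_depth_reaches_singletons(self, path4):
        tree = recursive_bisect(path4, seed=0)
        assert all(len(m) == 1 for m in tree.levels[-1])


class TestBisectCharacteristic:
    def test_endpoint_semantics(self, path4):
        tree = recursive_bisect(path4, seed=1)
        char = bisect_characteristic(path4, tree)
        last = char.points[-1]  # whole graph
        assert (last.B, last.P) == (4.0, 0.0)
        first = char.points[0]  # singletons: P = mean degree
        assert (first.B, first.P) == (1.0, pytest.approx(2 * 3 / 4))
        mid = [pt for pt in char.points if pt.B == 2.0]
        assert mid and mid[0].P == 1.0  # the depth-1 split {ab}|{cd}

    @staticmethod
    def straight_cut_oracle(n):
        """Optimal straight-line recursive bisection of the n x n lattice.

        Cutting every module along its longer side gives the minimal-cut
        hierarchy in closed form: per level, (n_modules, B, mean P).
        """
        a, b = n, n
        total_cut = 0
        n_mod = 1
        levels = []
        while a > 1:
            total_cut += n_mod * b  # each module pays one cut of length b
            n_mod *= 2
            a //= 2
            if b > a:
                a, b = b, a
            levels.append((n_mod, n * n / n_mod, 2 * total_cut / n_mod))
        return levels

    def test_grid_bisection_matches_straight_cut_oracle(self):
        """FM on the 32x32 lattice reaches the straight-cut hierarchy.

        Mean boundary edges per module at every level must be within 10%
        of the closed-form optimal rectangular partition (which includes
        the free-boundary saturation of the coarse levels), and the
        all-level Rent exponent must match the oracle's own fitted
        exponent.  Note the asymptotic boundary/area exponent 1/2 only
        emerges in the interior scales; the saturated coarse levels (the
        lattice analogue of Region II) pull the raw all-level fit well
        below it.
        """
        g = make_benchmark_graph("grid2d", n=32)
        assert g.number_of_nodes() == 1024
        tree = recursive_bisect(g, max_depth=8, epsilon=0.1, restarts=4, seed=7)
        char = bisect_characteristic(g, tree)
        oracle = {B: P for _, B, P in self.straight_cut_oracle(32)}
        checked = 0
        for pt in char.points:
            if pt.B in oracle and pt.P > 0:
                assert pt.P == pytest.approx(oracle[pt.B], rel=0.10)
                checked += 1
        assert checked >= 7
        import math
        from scipy import stats as sps
        measured_B = {pt.B for pt in char.points if pt.P > 0}
        ox = [math.log10(B) for _, B, P in self.straight_cut_oracle(32)
              if P > 0 and B in measured_B]
        oy = [math.log10(P) for _, B, P in self.straight_cut_oracle(32)
              if P > 0 and B in measured_B]
        oracle_p = sps.linregress(ox, oy).slope
        fit = fit_rent(char)
        assert fit.p == pytest.approx(oracle_p, abs=0.05)
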
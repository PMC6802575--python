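import networkx as nx
import numpy as np
import pytest

import funconn as fc
from funconn.connectome import BinaryGraph
from funconn.metrics import (assortativity, auc_over_densities, betweenness,
                             clustering_coefficient, metric_profile,
                             modularity, path_length_and_efficiency,
                             small_world_sigma)
from tests.conftest import graph_from_edges


def complete_graph(n):
    return graph_from_edges(n, [(i, j) for i in range(n)
                                for j in range(i + 1, n)])


def path_graph(n):
    return graph_from_edges(n, [(i, i + 1) for i in range(n - 1)])


def star_graph(n_leaves):
    return graph_from_edges(n_leaves + 1, [(0, i + 1)
                                           for i in range(n_leaves)])


class TestClustering:
    def test_complete_graph_is_one(self):
        c, per = clustering_coefficient(complete_graph(4))
        assert c == 1.0
        np.testing.assert_array_equal(per, np.ones(4))

    def test_triangle_free_is_zero(self):
        c, _ = clustering_coefficient(path_graph(4))
        assert c == 0.0

    def test_hand_enumerated_mixed_graph(self):
        g = graph_from_edges(4, [(0, 1), (0, 2), (1, 2), (1, 3)])
        c, per = clustering_coefficient(g)
        np.testing.assert_allclose(per, [1.0, 1 / 3, 1.0, 0.0])
        assert c == pytest.approx(7 / 12)


class TestPathsAndEfficiency:
    def test_complete_graph(self):
        ps = path_length_and_efficiency(complete_graph(5))
        assert ps.L == 1.0 and ps.E == 1.0 and ps.n_disconnected_pairs == 0

    def test_path_three(self):
        ps = path_length_and_efficiency(path_graph(3))
        assert ps.L == pytest.approx(4 / 3)
        assert ps.E == pytest.approx(5 / 6)

    def test_two_disjoint_edges(self):
        g = graph_from_edges(4, [(0, 1), (2, 3)])
        ps = path_length_and_efficiency(g)
        assert ps.E == pytest.approx(1 / 3)
        assert ps.L == 1.0
        assert ps.n_disconnected_pairs == 4

    def test_edgeless_graph_flagged(self):
        g = graph_from_edges(4, [])
        ps = path_length_and_efficiency(g)
        assert ps.E == 0.0
        assert np.isnan(ps.L)
        assert not ps.l_defined

    def test_adding_edge_monotone(self):
        rng = np.random.default_rng(0)
        for rep in range(10):
            n = 8
            G = nx.gnp_random_graph(n, 0.3, seed=int(rng.integers(1e6)))
            a = nx.to_numpy_array(G).astype(np.int8)
            g = BinaryGraph(a, a.sum() / 2 / (n * (n - 1) / 2),
                            [str(i) for i in range(n)])
            before = path_length_and_efficiency(g)
            free = [(i, j) for i in range(n) for j in range(i + 1, n)
                    if not a[i, j]]
            if not free:
                continue
            i, j = free[int(rng.integers(len(free)))]
            a2 = a.copy()
            a2[i, j] = a2[j, i] = 1
            g2 = BinaryGraph(a2, (a2.sum() / 2) / (n * (n - 1) / 2),
                             [str(i) for i in range(n)])
            after = path_length_and_efficiency(g2)
            assert after.E >= before.E - 1e-12


class TestModularity:
    def test_two_cliques_closed_form(self):
        edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        edges += [(i + 4, j + 4) for i, j in edges[:6]]
        g = graph_from_edges(8, edges)
        q, partition = modularity(g, seed=0)
        assert q == pytest.approx(0.5)
        comms = {frozenset(l for l, c in partition.items() if c == k)
                 for k in set(partition.values())}
        assert comms == {frozenset({"n0", "n1", "n2", "n3"}),
                         frozenset({"n4", "n5", "n6", "n7"})}

    def test_complete_graph_single_community(self):
        q, partition = modularity(complete_graph(6), seed=0)
        assert q == pytest.approx(0.0, abs=1e-12)
        assert len(set(partition.values())) == 1

    def test_edgeless_graph_raises(self):
        with pytest.raises(ValueError):
            modularity(graph_from_edges(3, []))

    def test_deterministic_under_seed(self):
        g = graph_from_edges(10, [(i, (i + 1) % 10) for i in range(10)]
                             + [(0, 5), (2, 7)])
        assert modularity(g, seed=3) == modularity(g, seed=3)

    def test_planted_two_block_recovery(self):
        """Louvain recovers a strongly planted 2-block partition."""
        hits = 0
        n_trials = 100
        for t in range(n_trials):
            rng = np.random.default_rng(1000 + t)
            n = 20
            block = np.arange(n) // 10
            u = np.triu(rng.random((n, n)), k=1)
            p = np.where(block[:, None] == block[None, :], 0.9, 0.05)
            a = ((u < p) & (u > 0)).astype(np.int8)
            a = a | a.T
            g = BinaryGraph(a, a.sum() / 2 / 190, [str(i) for i in range(n)])
            _, part = modularity(g, seed=t)
            labels = np.array([part[str(i)] for i in range(n)])
            agree = max(
                np.mean((labels == labels[0]) == (block == 0)),
                np.mean((labels == labels[0]) == (block == 1)))
            hits += (agree == 1.0)
        assert hits >= 95

    def test_q_at_least_trivial_partition(self):
        rng = np.random.default_rng(9)
        G = nx.gnp_random_graph(15, 0.3, seed=4)
        a = nx.to_numpy_array(G).astype(np.int8)
        g = BinaryGraph(a, a.sum() / 2 / 105, [str(i) for i in range(15)])
        q, _ = modularity(g, seed=0)
        assert q >= 0.0


class TestAssortativity:
    def test_star_is_minus_one(self):
        assert assortativity(star_graph(5)) == pytest.approx(-1.0)

    @pytest.mark.parametrize("g", [
        graph_from_edges(6, [(i, (i + 1) % 6) for i in range(6)]),  # ring
        graph_from_edges(6, [(0, 1), (1, 2), (0, 2),
                             (3, 4), (4, 5), (3, 5)]),  # two triangles
    ])
    def test_regular_graph_undefined(self, g):
        with pytest.warns(RuntimeWarning, match="undefined"):
            assert np.isnan(assortativity(g))

    def test_matches_networkx_on_random_graph(self):
        G = nx.gnp_random_graph(30, 0.2, seed=11)
        a = nx.to_numpy_array(G).astype(np.int8)
        g = BinaryGraph(a, a.sum() / 2 / 435, [str(i) for i in range(30)])
        assert assortativity(g) == pytest.approx(
            nx.degree_assortativity_coefficient(G), abs=1e-10)


class TestBetweenness:
    def test_star_center(self):
        b = betweenness(star_graph(7))
        assert b[0] == pytest.approx(1.0)
        np.testing.assert_allclose(b[1:], 0.0)

    def test_path_middle(self):
        b = betweenness(path_graph(3))
        assert b[1] == pytest.approx(1.0)

    def test_path_five_enumeration(self):
        b = betweenness(path_graph(5))
        np.testing.assert_allclose(b, [0, 3 / 6, 4 / 6, 3 / 6, 0])


class TestSigma:
    def test_null_preserves_degree_sequence(self):
        G = nx.gnp_random_graph(30, 0.25, seed=5)
        a = nx.to_numpy_array(G).astype(np.int8)
        g = BinaryGraph(a, a.sum() / 2 / 435, [str(i) for i in range(30)])
        deg = sorted(g.degrees())
        H = G.copy()
        nx.double_edge_swap(H, nswap=5 * g.n_edges,
                            max_tries=500 * g.n_edges, seed=1)
        assert sorted(d for _, d in H.degree()) == deg

    def test_lattice_is_small_world(self):
        W = nx.watts_strogatz_graph(100, 6, 0.1, seed=2)
        a = nx.to_numpy_array(W).astype(np.int8)
        g = BinaryGraph(a, a.sum() / 2 / 4950, [str(i) for i in range(100)])
        res = small_world_sigma(g, n_null=10, n_rewires_per_edge=5, seed=0)
        assert res.sigma > 1.5

    def test_reproducible_under_seed(self):
        G = nx.gnp_random_graph(40, 0.2, seed=6)
        a = nx.to_numpy_array(G).astype(np.int8)
        g = BinaryGraph(a, a.sum() / 2 / 780, [str(i) for i in range(40)])
        r1 = small_world_sigma(g, n_null=5, n_rewires_per_edge=5, seed=9)
        r2 = small_world_sigma(g, n_null=5, n_rewires_per_edge=5, seed=9)
        assert r1.sigma == r2.sigma

    def test_too_sparse_raises(self):
        with pytest.raises((ValueError, RuntimeError)):
            small_world_sigma(graph_from_edges(4, [(0, 1)]), n_null=2)


class TestAuc:
    def test_constant_over_default_sweep(self):
        d = np.arange(0.1, 0.501, 0.05)
        assert auc_over_densities(np.ones_like(d), d) == pytest.approx(0.4)

    def test_triangle_area(self):
        assert auc_over_densities([0, 1], [0.1, 0.5]) == pytest.approx(0.2)

    def test_trapezoid_arithmetic(self):
        assert auc_over_densities([2, 4, 4],
                                  [0.1, 0.2, 0.3]) == pytest.approx(0.7)

    def test_nan_restricts_range_with_warning(self):
        with pytest.warns(RuntimeWarning, match="contiguous"):
            out = auc_over_densities([np.nan, 1.0, 1.0, np.nan],
                                     [0.1, 0.2, 0.3, 0.4])
        assert out == pytest.approx(0.1)


def test_metric_profile_bounds(small_cohort):
    _, _, series, _, _ = small_cohort
    am = fc.correlation_matrix(series[0])
    g = fc.binarize_at_density(am, 0.2)
    prof = metric_profile(g, n_null=3, n_rewires_per_edge=3, seed=0)
    assert 0 <= prof.C <= 1
    assert 0 <= prof.E <= 1
    assert -0.5 <= prof.Q <= 1
    assert np.isnan(prof.r) or -1 <= prof.r <= 1
    assert prof.sigma > 0
    assert prof.L >= 1
    assert len(prof.nodal_degree) == g.n_nodes
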
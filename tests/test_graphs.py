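"""Fixed-density binarization and small-world network metrics."""

import networkx as nx
import numpy as np
import pytest
from numpy.testing import assert_allclose

from _oracles import clustering_oracle, eccentricity_oracle, path_length_oracle
from conftest import random_graph_edges
from jdnet.errors import UndefinedMetricError
from jdnet.graphs import (
    binarize_fixed_density,
    characteristic_path_length,
    clustering_coefficient,
    eccentricity,
    edge_count_for_density,
    network_metrics,
    random_reference,
    small_world_q,
)


def _sym(rng, n):
    w = rng.uniform(size=(n, n))
    w = np.triu(w, 1)
    w = w + w.T
    return w


class TestBinarize:
    def test_density_one_gives_complete_graph(self, rng):
        net = binarize_fixed_density(_sym(rng, 6), density=1.0)
        assert net.n_edges == 15
        assert nx.density(net.graph) == 1.0

    def test_study_scale_edge_count(self, rng):
        assert edge_count_for_density(128, 0.10) == 813
        net = binarize_fixed_density(_sym(rng, 128), density=0.10)
        assert net.n_edges == 813

    def test_strongest_pairs_selected(self):
        w = np.zeros((4, 4))
        w[np.triu_indices(4, 1)] = [0.9, 0.1, 0.2, 0.8, 0.3, 0.7]
        w = w + w.T
        net = binarize_fixed_density(w, density=0.5)
        assert set(map(frozenset, net.graph.edges)) == {
            frozenset((0, 1)), frozenset((1, 2)), frozenset((2, 3))
        }

    def test_quantized_ties_break_lexicographically(self):
        w = np.ones((5, 5)) - np.eye(5)  # all weights tied
        net = binarize_fixed_density(w, density=0.3)  # keep 3 of 10 pairs
        assert sorted(map(tuple, map(sorted, net.graph.edges))) == [
            (0, 1), (0, 2), (0, 3)
        ]


class TestMetricsExamples:
    def test_triangle_clustering(self):
        per, mean = clustering_coefficient(nx.cycle_graph(3))
        assert all(v == 1 for v in per.values()) and mean == 1

    def test_star_clustering(self):
        per, mean = clustering_coefficient(nx.star_graph(3))
        assert mean == 0

    def test_cycle_with_chord_clustering(self):
        g = nx.cycle_graph(4)
        g.add_edge(0, 2)
        per, mean = clustering_coefficient(g)
        assert_allclose([per[n] for n in range(4)], [2 / 3, 1, 2 / 3, 1])
        assert mean == pytest.approx(5 / 6)

    def test_complete_graph_path_length(self):
        assert characteristic_path_length(nx.complete_graph(5)) == 1

    def test_path_graph_path_length(self):
        assert characteristic_path_length(nx.path_graph(3)) == pytest.approx(4 / 3)

    def test_disjoint_triangles_use_largest_component(self):
        g = nx.union(nx.cycle_graph(3), nx.cycle_graph(3, nx.Graph), rename=("a", "b"))
        assert characteristic_path_length(g) == 1

    def test_empty_component_rejected(self):
        with pytest.raises(UndefinedMetricError):
            characteristic_path_length(nx.empty_graph(4))

    def test_complete_graph_eccentricity(self):
        per, mean = eccentricity(nx.complete_graph(6))
        assert all(v == 1 for v in per.values()) and mean == 1

    def test_path_graph_eccentricity(self):
        per, mean = eccentricity(nx.path_graph(3))
        assert [per[n] for n in range(3)] == [2, 1, 2]
        assert mean == pytest.approx(5 / 3)

    def test_isolated_node_eccentricity_zero(self):
        g = nx.path_graph(3)
        g.add_node(99)
        per, _ = eccentricity(g)
        assert per[99] == 0

    def test_diameter_summary_option(self):
        _, diam = eccentricity(nx.path_graph(4), summary="max")
        assert diam == 3


class TestSmallWorldQ:
    def test_unit_when_equal(self):
        assert small_world_q(0.3, 0.3, 2.0, 2.0) == 1

    def test_hand_arithmetic(self):
        assert small_world_q(0.4, 0.2, 2.0, 1.6) == pytest.approx(1.6)

    def test_zero_reference_rejected(self):
        with pytest.raises(UndefinedMetricError):
            small_world_q(0.4, 0.0, 2.0, 1.6)


class TestRandomReference:
    def test_complete_reference(self):
        ref = random_reference(6, 15, n_rand=3, seed=0)
        assert ref.c_random == 1 and ref.l_random == 1

    def test_er_clustering_near_density(self):
        ref = random_reference(128, 813, n_rand=10, seed=42)
        assert abs(ref.c_random - 0.10) < 0.02

    def test_seed_reproducibility(self):
        a = random_reference(30, 60, n_rand=5, seed=7)
        b = random_reference(30, 60, n_rand=5, seed=7)
        assert a.c_random == b.c_random and a.l_random == b.l_random


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(10))
    def test_metrics_match_floyd_warshall_oracles(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(3, 8))
        m = int(r.integers(1, n * (n - 1) // 2 + 1))
        edges = random_graph_edges(n, m, r)
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(edges)
        per_c, mean_c = clustering_coefficient(g)
        oc_per, oc_mean = clustering_oracle(n, edges)
        assert_allclose([per_c[v] for v in range(n)], oc_per)
        assert mean_c == pytest.approx(oc_mean)
        per_e, mean_e = eccentricity(g)
        oe_per, oe_mean = eccentricity_oracle(n, edges)
        assert [per_e[v] for v in range(n)] == oe_per
        assert mean_e == pytest.approx(oe_mean)
        try:
            expected = path_length_oracle(n, edges)
        except ValueError:
            with pytest.raises(UndefinedMetricError):
                characteristic_path_length(g)
        else:
            assert characteristic_path_length(g) == pytest.approx(expected)


class TestMonotonicity:
    @pytest.mark.parametrize("seed", range(5))
    def test_adding_edge_never_lengthens_paths(self, seed):
        r = np.random.default_rng(100 + seed)
        g = nx.connected_watts_strogatz_graph(12, 4, 0.3, seed=seed)
        before = dict(nx.all_pairs_shortest_path_length(g))
        _, ecc_before = eccentricity(g)
        missing = [e for e in nx.non_edges(g)]
        a, b = missing[int(r.integers(len(missing)))]
        g.add_edge(a, b)
        after = dict(nx.all_pairs_shortest_path_length(g))
        for i in g.nodes:
            for j in g.nodes:
                assert after[i][j] <= before[i][j]
        _, ecc_after = eccentricity(g)
        assert ecc_after <= ecc_before


def test_network_metrics_composite(rng):
    w = _sym(rng, 20)
    m = network_metrics(w, density=0.3, n_rand=5, seed=3)
    assert m.n_edges == edge_count_for_density(20, 0.3)
    assert 0 <= m.c_actual <= 1
    assert m.l_actual >= 1
    assert m.q == pytest.approx((m.c_actual / m.c_random) / (m.l_actual / m.l_random))
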
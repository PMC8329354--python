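"""Graph metrics against hand-worked examples and brute-force oracles."""

import numpy as np
import pytest

import oracles
from scnkit.metrics import (
    MetricUndefinedError,
    betweenness,
    characteristic_path_length,
    clustering_coefficients,
    degree_preserving_randomization,
    global_efficiency,
    global_metrics,
    local_efficiency,
    mean_clustering,
    nodal_efficiency,
    random_reference,
    small_world,
)


def adj_from_edges(n, edges):
    a = np.zeros((n, n), dtype=np.int8)
    for u, v in edges:
        a[u, v] = a[v, u] = 1
    return a


K3 = adj_from_edges(3, [(0, 1), (1, 2), (0, 2)])
PATH3 = adj_from_edges(3, [(0, 1), (1, 2)])
K4 = adj_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
STAR5 = adj_from_edges(5, [(0, i) for i in range(1, 5)])
C4 = adj_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])


class TestClustering:
    def test_triangle_is_fully_clustered(self):
        assert clustering_coefficients(K3) == pytest.approx([1, 1, 1])
        assert mean_clustering(K3) == 1.0

    def test_path_has_zero_clustering(self):
        assert mean_clustering(PATH3) == 0.0

    def test_k4_with_pendant_chain_matches_triangle_enumeration(self):
        # K4 on {0..3} plus pendant edges 3-4, 4-5
        a = adj_from_edges(6, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3),
                               (3, 4), (4, 5)])
        assert clustering_coefficients(a) == pytest.approx(oracles.bf_clustering(a))


class TestPathLength:
    def test_complete_graph_unit_length(self):
        assert characteristic_path_length(K4) == 1.0

    def test_three_node_path(self):
        assert characteristic_path_length(PATH3) == pytest.approx(4 / 3)

    def test_disconnected_pairs_excluded_from_average(self):
        two_k2 = adj_from_edges(4, [(0, 1), (2, 3)])
        assert characteristic_path_length(two_k2) == 1.0

    def test_edgeless_graph_is_undefined(self):
        with pytest.raises(MetricUndefinedError):
            characteristic_path_length(np.zeros((4, 4), dtype=int))


class TestEfficiency:
    def test_complete_graph_efficiency_one(self):
        assert global_efficiency(K4) == 1.0

    def test_edgeless_graph_efficiency_zero(self):
        assert global_efficiency(np.zeros((5, 5), dtype=int)) == 0.0

    def test_three_node_path_value(self):
        assert global_efficiency(PATH3) == pytest.approx(5 / 6)

    def test_local_efficiency_of_k4_is_one(self):
        per, mean = local_efficiency(K4)
        assert per == pytest.approx([1, 1, 1, 1])
        assert mean == 1.0

    def test_star_graph_local_efficiency_zero(self):
        per, mean = local_efficiency(STAR5)
        assert mean == 0.0

    def test_k4_plus_pendant_matches_brute_force(self):
        a = adj_from_edges(5, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3),
                               (3, 4)])
        per, _ = local_efficiency(a)
        assert per == pytest.approx(oracles.bf_local_efficiency(a))
        assert nodal_efficiency(a) == pytest.approx(oracles.bf_nodal_efficiency(a))

    def test_global_efficiency_monotone_under_edge_addition(self):
        rng = np.random.default_rng(4)
        a = adj_from_edges(8, [(0, 1), (2, 3), (4, 5)])
        prev = global_efficiency(a)
        iu = list(zip(*np.triu_indices(8, 1)))
        rng.shuffle(iu)
        for u, v in iu:
            if a[u, v]:
                continue
            a[u, v] = a[v, u] = 1
            cur = global_efficiency(a)
            assert cur >= prev - 1e-12
            prev = cur


class TestBetweenness:
    def test_star_center_has_maximal_betweenness(self):
        norm, raw = betweenness(STAR5)
        assert norm[0] == pytest.approx(1.0)
        assert norm[1:] == pytest.approx([0, 0, 0, 0])
        assert raw[0] == pytest.approx(6.0)  # C(4,2) pairs routed via center

    def test_cycle_c4_by_path_enumeration(self):
        # each node lies on 1 of the 2 shortest paths of the opposite pair:
        # raw 0.5, normalized 0.5/3
        norm, raw = betweenness(C4)
        assert raw == pytest.approx([0.5] * 4)
        assert norm == pytest.approx([0.5 / 3] * 4)

    def test_complete_graph_all_zero(self):
        norm, _ = betweenness(K4)
        assert norm == pytest.approx([0, 0, 0, 0])


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_all_metrics_match_brute_force_on_random_graphs(self, seed):
        rng = np.random.default_rng(1000 + seed)
        for _ in range(5):
            a = oracles.random_connected_graph(rng)
            assert clustering_coefficients(a) == pytest.approx(oracles.bf_clustering(a))
            assert characteristic_path_length(a) == pytest.approx(oracles.bf_path_length(a))
            assert global_efficiency(a) == pytest.approx(oracles.bf_global_efficiency(a))
            assert nodal_efficiency(a) == pytest.approx(oracles.bf_nodal_efficiency(a))
            per, _ = local_efficiency(a)
            assert per == pytest.approx(oracles.bf_local_efficiency(a))
            norm, _ = betweenness(a)
            assert norm == pytest.approx(oracles.bf_betweenness(a))

    def test_metrics_invariant_under_node_relabeling(self):
        rng = np.random.default_rng(77)
        a = oracles.random_connected_graph(rng)
        perm = rng.permutation(a.shape[0])
        ap = a[np.ix_(perm, perm)]
        assert mean_clustering(a) == pytest.approx(mean_clustering(ap))
        assert characteristic_path_length(a) == pytest.approx(characteristic_path_length(ap))
        assert global_efficiency(a) == pytest.approx(global_efficiency(ap))
        assert sorted(nodal_efficiency(a)) == pytest.approx(sorted(nodal_efficiency(ap)))


class TestRandomReference:
    def test_degree_sequence_preserved_exactly(self):
        rng = np.random.default_rng(12)
        a = (rng.random((30, 30)) < 0.2).astype(int)
        a = np.triu(a, 1)
        a = a + a.T
        ref = random_reference(a, n_random=20, seed=5)
        deg = np.sort(a.sum(axis=0))
        for _ in range(3):  # re-generate, degree check on fresh references
            ar, _ = degree_preserving_randomization(a, np.random.default_rng(rng.integers(1 << 30)))
            assert (np.sort(ar.sum(axis=0)) == deg).all()
            assert (ar == ar.T).all() and np.diag(ar).sum() == 0

    def test_complete_graph_cannot_be_rewired_and_is_flagged(self):
        ref = random_reference(K4, n_random=5, seed=0)
        assert ref.flagged
        assert (ref.c_rand == 1.0).all()
        sw = small_world(K4, n_random=5, seed=0)
        assert sw.gamma == sw.lambda_ == sw.sigma == 1.0

    def test_same_seed_reproduces_reference_set(self):
        rng = np.random.default_rng(2)
        a = (rng.random((68, 68)) < 0.09).astype(int)
        a = np.triu(a, 1)
        a = a + a.T
        r1 = random_reference(a, n_random=10, seed=99)
        r2 = random_reference(a, n_random=10, seed=99)
        assert (r1.c_rand == r2.c_rand).all()
        assert (r1.l_rand == r2.l_rand).all()

    def test_sigma_is_exactly_gamma_over_lambda(self):
        rng = np.random.default_rng(8)
        a = (rng.random((40, 40)) < 0.15).astype(int)
        a = np.triu(a, 1)
        a = a + a.T
        sw = small_world(a, n_random=10, seed=3)
        assert sw.sigma == sw.gamma / sw.lambda_

    def test_ring_lattice_small_world_sigma_above_one(self):
        # Watts-Strogatz-style: 68-node ring, 6 neighbours, 5% rewired
        import networkx as nx

        g = nx.watts_strogatz_graph(68, 6, 0.05, seed=4)
        a = nx.to_numpy_array(g, dtype=int)
        sw = small_world(a, n_random=30, seed=6)
        assert sw.sigma > 1.0


def test_global_metrics_bundle_is_consistent():
    rng = np.random.default_rng(31)
    a = (rng.random((20, 20)) < 0.25).astype(int)
    a = np.triu(a, 1)
    a = a + a.T
    gm = global_metrics(a, n_random=10, seed=2)
    assert 0 <= gm.C <= 1 and 0 <= gm.E_global <= 1 and 0 <= gm.E_local <= 1
    assert gm.sigma == pytest.approx(gm.gamma / gm.lambda_, rel=1e-15)
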
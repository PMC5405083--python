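"""Weighted small-world panel: clustering, paths, nulls, sigma, cost."""


import numpy as np
import networkx as nx
import pytest

import cerenet
from conftest import random_weighted_graph


def triangle(w=0.7, n=3):
    weights = np.full((n, n), w)
    np.fill_diagonal(weights, 0.0)
    return weights


def path_graph(weights_list):
    n = len(weights_list) + 1
    weights = np.zeros((n, n))
    for i, w in enumerate(weights_list):
        weights[i, i + 1] = weights[i + 1, i] = w
    return weights


class TestWeightedClustering:
    def test_equal_weight_triangle_is_one(self):
        c_i, c_w = cerenet.weighted_clustering(triangle())
        np.testing.assert_allclose(c_i, 1.0)
        assert c_w == pytest.approx(1.0)

    def test_triangle_free_graph_is_zero(self):
        c_i, c_w = cerenet.weighted_clustering(path_graph([0.5, 0.8, 0.3]))
        np.testing.assert_allclose(c_i, 0.0)
        assert c_w == 0.0

    def test_matches_triple_loop_oracle(self, rng):
        # oracle: direct triple loop over the geometric-mean triangle formula
        for _ in range(50):
            weights = random_weighted_graph(rng, 6, density=0.7,
                                            ensure_connected=False)
            c_i, c_w = cerenet.weighted_clustering(weights)
            w_max = weights.max()
            scaled = weights / w_max if w_max > 0 else weights
            n = 6
            for i in range(n):
                t_i = 0.0
                for j in range(n):
                    for k in range(n):
                        t_i += (scaled[i, j] * scaled[j, k] * scaled[k, i]) ** (1 / 3)
                t_i /= 2.0
                k_i = int((weights[i] > 0).sum())
                expected = 2 * t_i / (k_i * (k_i - 1)) if k_i >= 2 else 0.0
                assert c_i[i] == pytest.approx(expected, abs=1e-10)

    def test_bounded_by_unit_interval(self, rng):
        for _ in range(20):
            weights = random_weighted_graph(rng, 8, density=0.6,
                                            ensure_connected=False)
            c_i, _ = cerenet.weighted_clustering(weights)
            assert np.all(c_i >= 0) and np.all(c_i <= 1 + 1e-12)

    def test_scale_invariance(self, rng):
        weights = random_weighted_graph(rng, 7)
        base, _ = cerenet.weighted_clustering(weights)
        scaled, _ = cerenet.weighted_clustering(0.37 * weights)
        np.testing.assert_allclose(scaled, base, atol=1e-12)


class TestShortestPaths:
    def test_single_edge_reciprocal(self):
        dists = cerenet.shortest_paths(path_graph([0.25]))
        assert dists[0, 1] == pytest.approx(4.0)

    def test_complete_unit_weights(self):
        weights = triangle(1.0, n=5)
        dists = cerenet.shortest_paths(weights)
        off = dists[~np.eye(5, dtype=bool)]
        np.testing.assert_allclose(off, 1.0)

    def test_matches_simple_path_enumeration(self, rng):
        # oracle: exhaustive enumeration of simple paths
        for _ in range(50):
            weights = random_weighted_graph(rng, 5, density=0.7)
            dists = cerenet.shortest_paths(weights)
            graph = nx.from_numpy_array(weights)
            for s in range(5):
                for t in range(5):
                    if s == t:
                        continue
                    best = min(
                        sum(1.0 / weights[u, v] for u, v in zip(p, p[1:]))
                        for p in nx.all_simple_paths(graph, s, t)
                    )
                    assert dists[s, t] == pytest.approx(best, rel=1e-10)

    def test_path_length_scales_inversely_with_weights(self, rng):
        weights = random_weighted_graph(rng, 6)
        l_base = cerenet.characteristic_path_length(cerenet.shortest_paths(weights))
        l_scaled = cerenet.characteristic_path_length(
            cerenet.shortest_paths(0.5 * weights)
        )
        assert l_scaled == pytest.approx(2.0 * l_base)


class TestCharacteristicPathLength:
    def test_complete_unit_graph(self):
        dists = cerenet.shortest_paths(triangle(1.0, n=6))
        assert cerenet.characteristic_path_length(dists) == pytest.approx(1.0)

    def test_three_node_path_by_hand(self):
        # the 6 ordered pairs have distances 1,1,1,1,2,2 -> mean 4/3
        dists = cerenet.shortest_paths(path_graph([1.0, 1.0]))
        assert cerenet.characteristic_path_length(dists) == pytest.approx(4 / 3)

    def test_two_nodes_half_weight(self):
        dists = cerenet.shortest_paths(path_graph([0.5]))
        assert cerenet.characteristic_path_length(dists) == pytest.approx(2.0)

    def test_disconnected_raises_without_fallback(self):
        weights = np.zeros((4, 4))
        weights[0, 1] = weights[1, 0] = 0.5
        weights[2, 3] = weights[3, 2] = 0.5
        dists = cerenet.shortest_paths(weights)
        with pytest.raises(ValueError, match="disconnected"):
            cerenet.characteristic_path_length(dists)
        harmonic = cerenet.characteristic_path_length(dists, harmonic_fallback=True)
        assert np.isfinite(harmonic)


class TestConnectivityCost:
    def test_uniform_complete_graph(self):
        assert cerenet.connectivity_cost(triangle(0.4, n=9)) == pytest.approx(0.4)

    def test_empty_graph_is_zero(self):
        assert cerenet.connectivity_cost(np.zeros((5, 5))) == 0.0

    def test_matches_direct_sum(self, rng):
        weights = random_weighted_graph(rng, 4, ensure_connected=False)
        expected = sum(
            weights[i, j] for i in range(4) for j in range(4) if i != j
        ) / 12
        assert cerenet.connectivity_cost(weights) == pytest.approx(expected)

    def test_permutation_invariance_and_edge_sum_identity(self, rng):
        weights = random_weighted_graph(rng, 6)
        perm = rng.permutation(6)
        assert cerenet.connectivity_cost(weights[np.ix_(perm, perm)]) == pytest.approx(
            cerenet.connectivity_cost(weights)
        )
        edge_sum = np.triu(weights, 1).sum()
        assert cerenet.connectivity_cost(weights) == pytest.approx(
            2 * edge_sum / (6 * 5)
        )

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            cerenet.connectivity_cost(np.zeros((1, 1)))


class TestNullEnsemble:
    def test_complete_graph_nulls_equal_input_with_warning(self):
        weights = triangle(0.5, n=6)
        with pytest.warns(UserWarning, match="rewirable"):
            nulls = cerenet.null_ensemble(weights, n_null=5, seed=1)
        for null in nulls:
            np.testing.assert_array_equal(null, weights)

    def test_degree_sequence_preserved(self, rng):
        weights = random_weighted_graph(rng, 10, density=0.4)
        degrees = (weights > 0).sum(axis=1)
        for null in cerenet.null_ensemble(weights, n_null=10, seed=2):
            np.testing.assert_array_equal((null > 0).sum(axis=1), degrees)

    def test_weight_multiset_preserved(self, rng):
        # oracle: sorted weight lists must match exactly
        weights = random_weighted_graph(rng, 10, density=0.4)
        original = np.sort(weights[np.triu_indices(10, 1)])
        for null in cerenet.null_ensemble(weights, n_null=10, seed=3):
            np.testing.assert_allclose(
                np.sort(null[np.triu_indices(10, 1)]), original
            )

    def test_nulls_are_symmetric_and_actually_rewired(self, rng):
        weights = random_weighted_graph(rng, 12, density=0.4)
        nulls = cerenet.null_ensemble(weights, n_null=5, seed=4)
        assert any(not np.array_equal(null, weights) for null in nulls)
        for null in nulls:
            np.testing.assert_array_equal(null, null.T)

    def test_seeded_and_reproducible(self, rng):
        weights = random_weighted_graph(rng, 8, density=0.5)
        a = cerenet.null_ensemble(weights, n_null=3, seed=9)
        b = cerenet.null_ensemble(weights, n_null=3, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)


class TestSmallWorldness:
    def test_self_ensemble_gives_unit_ratios(self, rng):
        weights = random_weighted_graph(rng, 8)
        result = cerenet.small_worldness(weights, ensemble=[weights.copy()] * 4)
        assert result.gamma == pytest.approx(1.0)
        assert result.lam == pytest.approx(1.0)
        assert result.sigma == pytest.approx(1.0)

    def test_sigma_is_gamma_over_lambda(self, rng):
        weights = random_weighted_graph(rng, 10, density=0.5)
        result = cerenet.small_worldness(weights, n_null=20, seed=5)
        assert result.sigma == pytest.approx(result.gamma / result.lam)
        assert result.gamma == pytest.approx(result.c_w / result.c_w_rand)
        assert result.lam == pytest.approx(result.l_w / result.l_w_rand)

    def test_modular_clustered_graph_is_small_world(self):
        weights = cerenet.modular_small_world_graph(seed=0)
        result = cerenet.small_worldness(weights, n_null=100, seed=1)
        assert result.sigma > 1.0

    def test_lattice_graph_has_high_segregation(self):
        # a ring lattice is the maximally clustered reference: gamma >> 1
        weights = cerenet.ring_lattice_graph(seed=0, neighbours=4, n_shortcuts=5)
        result = cerenet.small_worldness(weights, n_null=50, seed=2)
        assert result.gamma > 1.5

    def test_empty_ensemble_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            cerenet.small_worldness(random_weighted_graph(rng, 5), ensemble=[])


def test_edge_capacity_closed_form():
    assert cerenet.max_edges(27) == 351
    assert cerenet.max_edges(2) == 1
    assert cerenet.max_edges(0) == 0
    with pytest.raises(ValueError):
        cerenet.max_edges(-1)
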
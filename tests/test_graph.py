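"""Graph-theory metrics against independent oracles and analytic values."""

import numpy as np
import pytest

from nirsnet import (
    BinaryNetwork,
    ConnectivityMatrix,
    characteristic_path_length,
    clustering_coefficient,
    compute_metrics,
    degree_centrality,
    global_efficiency,
    local_efficiency,
    nodal_efficiency,
    rewire_degree_preserving,
    shortest_path_lengths,
    small_worldness,
    sparsity_sweep,
)


def complete(n):
    a = np.ones((n, n)) - np.eye(n)
    return BinaryNetwork(adjacency=a)


def star(n):
    a = np.zeros((n, n))
    a[0, 1:] = a[1:, 0] = 1
    return BinaryNetwork(adjacency=a)


def path_graph(n):
    a = np.zeros((n, n))
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1
    return BinaryNetwork(adjacency=a)


def cycle(n):
    a = np.zeros((n, n))
    for i in range(n):
        a[i, (i + 1) % n] = a[(i + 1) % n, i] = 1
    return BinaryNetwork(adjacency=a)


def random_net(rng, n, p):
    a = (rng.random((n, n)) < p).astype(float)
    a = np.triu(a, k=1)
    a = a + a.T
    return BinaryNetwork(adjacency=a)


def floyd_warshall(a):
    """Independent O(n^3) all-pairs shortest paths."""
    n = a.shape[0]
    d = np.where(a > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_force_clustering(a):
    """Triangle counting over all neighbor pairs."""
    n = a.shape[0]
    c = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(a[i])
        z = nb.size
        if z < 2:
            continue
        links = 0
        for u in range(z):
            for v in range(u + 1, z):
                links += a[nb[u], nb[v]]
        c[i] = 2 * links / (z * (z - 1))
    return c


class TestShortestPaths:
    def test_complete_graph_all_distance_one(self):
        d = shortest_path_lengths(complete(5))
        assert np.all(d[~np.eye(5, dtype=bool)] == 1)

    def test_path_graph_end_to_end(self):
        d = shortest_path_lengths(path_graph(4))
        assert d[0, 3] == 3

    def test_unreachable_is_infinite(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 1
        d = shortest_path_lengths(BinaryNetwork(adjacency=a))
        assert np.isinf(d[0, 2])

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_floyd_warshall(self, seed):
        rng = np.random.default_rng(seed)
        net = random_net(rng, int(rng.integers(4, 13)), rng.uniform(0.1, 0.7))
        assert np.array_equal(shortest_path_lengths(net), floyd_warshall(net.adjacency))


class TestDegree:
    def test_complete_20(self):
        assert np.all(degree_centrality(complete(20)) == 19)

    def test_empty(self):
        net = BinaryNetwork(adjacency=np.zeros((6, 6)))
        assert np.all(degree_centrality(net) == 0)

    def test_star_6(self):
        d = degree_centrality(star(6))
        assert d[0] == 5 and np.all(d[1:] == 1)


class TestNodalEfficiency:
    def test_complete_graph_unity(self):
        assert np.allclose(nodal_efficiency(complete(7)), 1.0)

    def test_isolated_node_zero(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 1
        e = nodal_efficiency(BinaryNetwork(adjacency=a))
        assert e[2] == 0.0 and e[3] == 0.0

    def test_star_5_hand_computed(self):
        e = nodal_efficiency(star(5))
        assert e[0] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(e[1:], (1 + 3 * 0.5) / 4, atol=1e-12)


class TestClustering:
    def test_triangle_all_one(self):
        c, k = clustering_coefficient(complete(3))
        assert np.allclose(c, 1.0) and k == pytest.approx(1.0)

    def test_star_all_zero(self):
        c, k = clustering_coefficient(star(6))
        assert np.allclose(c, 0.0) and k == 0.0

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_triangle_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        net = random_net(rng, int(rng.integers(4, 13)), rng.uniform(0.2, 0.8))
        c, _ = clustering_coefficient(net)
        assert np.allclose(c, brute_force_clustering(net.adjacency), atol=1e-12)


class TestEfficiencies:
    def test_complete_graph(self):
        assert global_efficiency(complete(6)) == pytest.approx(1.0, abs=1e-12)

    def test_four_cycle_hand_computed(self):
        assert global_efficiency(cycle(4)) == pytest.approx((1 + 1 + 0.5) / 3, abs=1e-12)

    @pytest.mark.parametrize("seed", range(50))
    def test_global_equals_mean_nodal(self, seed):
        rng = np.random.default_rng(200 + seed)
        net = random_net(rng, int(rng.integers(4, 13)), rng.uniform(0.1, 0.8))
        assert global_efficiency(net) == pytest.approx(
            nodal_efficiency(net).mean(), abs=1e-12
        )

    def test_local_efficiency_triangle(self):
        assert local_efficiency(complete(3)) == pytest.approx(1.0, abs=1e-12)

    def test_local_efficiency_star_zero(self):
        assert local_efficiency(star(6)) == 0.0

    def test_local_efficiency_empty_zero(self):
        assert local_efficiency(BinaryNetwork(adjacency=np.zeros((5, 5)))) == 0.0

    def test_matches_networkx_on_random_graphs(self):
        nx = pytest.importorskip("networkx")
        for seed in range(10):
            rng = np.random.default_rng(300 + seed)
            net = random_net(rng, 10, 0.4)
            g = nx.from_numpy_array(net.adjacency)
            assert global_efficiency(net) == pytest.approx(
                nx.global_efficiency(g), abs=1e-12
            )
            c, _ = clustering_coefficient(net)
            nxc = nx.clustering(g)
            assert np.allclose(c, [nxc[i] for i in range(10)], atol=1e-12)


class TestBounds:
    @pytest.mark.parametrize("seed", range(0, 200, 4))
    def test_metric_ranges(self, seed):
        rng = np.random.default_rng(400 + seed)
        n = int(rng.integers(4, 16))
        net = random_net(rng, n, rng.uniform(0.05, 0.9))
        m = compute_metrics(net)
        assert 0 <= m.global_efficiency <= 1
        assert 0 <= m.local_efficiency <= 1
        assert np.all((m.nodal_efficiency >= 0) & (m.nodal_efficiency <= 1))
        assert np.all((m.clustering >= 0) & (m.clustering <= 1))
        assert np.all((m.degree >= 0) & (m.degree <= n - 1))


class TestSmallWorldness:
    def test_rewiring_preserves_degrees(self, rng):
        net = random_net(rng, 15, 0.3)
        null = rewire_degree_preserving(net, rng)
        assert np.array_equal(
            degree_centrality(net), degree_centrality(null)
        )
        assert not np.array_equal(net.adjacency, null.adjacency)

    def test_dense_random_graph_sigma_near_one(self):
        rng = np.random.default_rng(7)
        net = random_net(rng, 30, 0.5)
        sw = small_worldness(net, n_nulls=50, seed=11)
        assert 0.8 <= sw.sigma <= 1.2

    def test_ring_lattice_with_shortcuts_is_small_world(self):
        n = 100
        a = np.zeros((n, n))
        for i in range(n):
            for d in (1, 2):
                a[i, (i + d) % n] = a[(i + d) % n, i] = 1
        rng = np.random.default_rng(3)
        edges = list(zip(*np.nonzero(np.triu(a, k=1))))
        # rewire 5% of edges to random shortcuts
        k = max(1, int(0.05 * len(edges)))
        for idx in rng.choice(len(edges), size=k, replace=False):
            i, j = edges[idx]
            m = int(rng.integers(0, n))
            if m != i and a[i, m] == 0:
                a[i, j] = a[j, i] = 0
                a[i, m] = a[m, i] = 1
        sw = small_worldness(BinaryNetwork(adjacency=a), n_nulls=20, seed=5)
        assert sw.sigma > 1.0

    def test_normalized_sigma_bounded(self):
        rng = np.random.default_rng(9)
        sw = small_worldness(random_net(rng, 20, 0.4), n_nulls=20, seed=1)
        assert 0.0 < sw.sigma_normalized < 1.0
        assert sw.sigma_normalized == pytest.approx(sw.sigma / (1 + sw.sigma))

    def test_too_few_edges_flagged_undefined(self):
        a = np.zeros((5, 5))
        a[0, 1] = a[1, 0] = 1
        sw = small_worldness(BinaryNetwork(adjacency=a), n_nulls=10, seed=0)
        assert not sw.defined

    def test_determinism(self):
        rng = np.random.default_rng(13)
        net = random_net(rng, 20, 0.4)
        s1 = small_worldness(net, n_nulls=20, seed=42).sigma
        s2 = small_worldness(net, n_nulls=20, seed=42).sigma
        assert s1 == s2


class TestSparsitySweep:
    def _matrix(self, rng):
        x = rng.normal(size=(300, 20))
        from nirsnet import fc_matrix

        return fc_matrix(x)

    def test_default_grid_has_nine_levels(self, rng):
        sw = sparsity_sweep(self._matrix(rng), n_nulls=0)
        assert np.allclose(sw.grid, np.arange(0.50, 0.901, 0.05))
        assert len(sw.metrics) == 9

    def test_global_efficiency_nondecreasing(self, rng):
        sw = sparsity_sweep(self._matrix(rng), n_nulls=0)
        eg = sw.summary()["global_efficiency"].to_numpy()
        assert np.all(np.diff(eg) >= -1e-12)

    def test_levels_match_single_calls(self, rng):
        from nirsnet import binarize_sparsity

        m = self._matrix(rng)
        sw = sparsity_sweep(m, n_nulls=0)
        for s, ms in zip(sw.grid, sw.metrics):
            net = BinaryNetwork.from_connectivity(binarize_sparsity(m, float(s)))
            assert compute_metrics(net).global_efficiency == pytest.approx(
                ms.global_efficiency, abs=1e-12
            )

    def test_mean_sd_summary_shape(self, rng):
        sw = sparsity_sweep(self._matrix(rng), n_nulls=10, seed=3)
        df = sw.mean_sd()
        assert "small_worldness" in df.index
        assert set(df.columns) == {"mean", "sd"}

    def test_invalid_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            sparsity_sweep(self._matrix(rng), grid=np.array([0.9, 0.5]), n_nulls=0)


def test_characteristic_path_length_on_cycle():
    # C5: distances 1,1,2,2 per node -> mean 1.5
    assert characteristic_path_length(cycle(5)) == pytest.approx(1.5)
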
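"""Thresholding, nodal/global graph metrics, null rewiring, and AUC."""

import numpy as np
import pytest

from iscn.graphs import (
    BinaryGraph,
    DensitySchedule,
    auc_over_densities,
    characteristic_path_length,
    metric_curves,
    nodal_metrics,
    rewire_preserving_degree,
    small_world,
    threshold_by_density,
)
from iscn.network import ConnectivityMatrix

from oracles import (
    brute_force_char_path_length,
    brute_force_nodal_metrics,
    random_graph_adj,
)


def similarity_matrix(rng, n):
    w = rng.uniform(0.01, 1.0, (n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 1.0)
    return ConnectivityMatrix("s", w, [f"R{i:03d}" for i in range(n)])


def graph_from_edges(n, edges):
    adj = np.zeros((n, n), bool)
    for a, b in edges:
        adj[a, b] = adj[b, a] = True
    return BinaryGraph(adjacency=adj)


class TestThreshold:
    def test_edge_count_at_default_density(self, rng):
        g = threshold_by_density(similarity_matrix(rng, 90), 0.10)
        assert g.n_edges == 400  # floor(0.10 * 4005)
        assert g.degrees.sum() == 2 * g.n_edges  # handshake lemma

    def test_high_density_gives_complete_graph(self, rng):
        g = threshold_by_density(similarity_matrix(rng, 8), 0.999)
        assert g.n_edges == 27  # floor(0.999 * 28)

    def test_edge_sets_nested_in_density(self, rng):
        m = similarity_matrix(rng, 30)
        prev = None
        for d in DensitySchedule().densities:
            edges = {tuple(e) for e in threshold_by_density(m, float(d)).edges}
            if prev is not None:
                assert prev <= edges
            prev = edges

    def test_tie_break_deterministic(self):
        values = np.full((5, 5), 0.5)
        np.fill_diagonal(values, 1.0)
        m = ConnectivityMatrix("s", values, list("abcde"))
        g = threshold_by_density(m, 0.3)  # 3 of 10 equal weights
        assert [tuple(e) for e in g.edges] == [(0, 1), (0, 2), (0, 3)]

    def test_zero_edge_density_rejected(self, rng):
        with pytest.raises(ValueError, match="0 edges"):
            threshold_by_density(similarity_matrix(rng, 5), 0.05)


class TestNodalMetrics:
    def test_complete_graph(self):
        g = graph_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
        m = nodal_metrics(g)
        np.testing.assert_array_equal(m.degree, [3, 3, 3, 3])
        np.testing.assert_allclose(m.clustering, 1.0)
        np.testing.assert_allclose(m.efficiency, 1.0)
        np.testing.assert_allclose(m.path_length, 1.0)
        assert characteristic_path_length(g) == 1.0

    def test_three_leaf_star(self):
        g = graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        m = nodal_metrics(g)
        assert m.degree[0] == 3
        assert m.efficiency[1] == pytest.approx(2 / 3)  # (1 + 1/2 + 1/2) / 3
        assert m.clustering[1] == 0.0
        assert characteristic_path_length(g) == pytest.approx(1.5)

    def test_path_graph_characteristic_length(self):
        g = graph_from_edges(3, [(0, 1), (1, 2)])
        assert characteristic_path_length(g) == pytest.approx(4 / 3)

    def test_isolated_node_conventions(self):
        g = graph_from_edges(3, [(0, 1)])
        m = nodal_metrics(g)
        assert np.isnan(m.path_length[2])
        assert m.efficiency[2] == 0.0

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_on_random_graphs(self, trial):
        rng = np.random.default_rng(100 + trial)
        adj = random_graph_adj(rng, int(rng.integers(5, 15)), rng.uniform(0.2, 0.7))
        g = BinaryGraph(adjacency=adj)
        metrics = nodal_metrics(g)
        deg, clu, pl, eff = brute_force_nodal_metrics(adj)
        np.testing.assert_array_equal(metrics.degree, deg)
        np.testing.assert_allclose(metrics.clustering, clu, rtol=1e-12)
        np.testing.assert_allclose(metrics.path_length, pl, rtol=1e-12)
        np.testing.assert_allclose(metrics.efficiency, eff, rtol=1e-12)
        if np.isfinite(pl).any() and (deg > 0).all():
            assert characteristic_path_length(g) == pytest.approx(
                brute_force_char_path_length(adj), rel=1e-12
            )


class TestRewiring:
    def test_degree_sequence_and_edge_count_preserved(self, rng):
        for _ in range(10):
            adj = random_graph_adj(np.random.default_rng(rng.integers(1 << 30)), 15, 0.3)
            g = BinaryGraph(adjacency=adj)
            r = rewire_preserving_degree(g, seed=3)
            np.testing.assert_array_equal(r.degrees, g.degrees)
            assert r.n_edges == g.n_edges

    def test_reproducible_from_seed(self, rng):
        g = BinaryGraph(adjacency=random_graph_adj(rng, 20, 0.3))
        a = rewire_preserving_degree(g, seed=7)
        b = rewire_preserving_degree(g, seed=7)
        c = rewire_preserving_degree(g, seed=8)
        np.testing.assert_array_equal(a.adjacency, b.adjacency)
        assert not np.array_equal(a.adjacency, c.adjacency)

    def test_star_has_no_valid_swap(self):
        g = graph_from_edges(5, [(0, i) for i in range(1, 5)])
        with pytest.warns(UserWarning, match="no valid"):
            r = rewire_preserving_degree(g, seed=0)
        np.testing.assert_array_equal(r.adjacency, g.adjacency)

    def test_matches_networkx_swap_ensemble_clustering(self):
        """Same null model as an independent Maslov-Sneppen implementation."""
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(5)
        g = BinaryGraph(adjacency=random_graph_adj(rng, 20, 0.3))
        ours = np.array([
            float(np.mean(nodal_metrics(rewire_preserving_degree(g, seed=k)).clustering))
            for k in range(100)
        ])
        base = nx.from_numpy_array(g.adjacency)
        theirs = []
        for k in range(100):
            h = base.copy()
            nx.double_edge_swap(h, nswap=10 * g.n_edges, max_tries=10**6, seed=k)
            theirs.append(float(np.mean(list(nx.clustering(h).values()))))
        se = np.sqrt(ours.var() / 100 + np.var(theirs) / 100)
        assert abs(ours.mean() - np.mean(theirs)) < 3 * se


def ring_lattice_with_shortcuts(n, k, p_shortcut, seed):
    rng = np.random.default_rng(seed)
    adj = np.zeros((n, n), bool)
    for i in range(n):
        for off in range(1, k // 2 + 1):
            j = (i + off) % n
            adj[i, j] = adj[j, i] = True
    edges = np.argwhere(np.triu(adj, 1))
    for a, b in edges:
        if rng.random() < p_shortcut:
            candidates = np.nonzero(~adj[a])[0]
            candidates = candidates[candidates != a]
            new = rng.choice(candidates)
            adj[a, b] = adj[b, a] = False
            adj[a, new] = adj[new, a] = True
    return BinaryGraph(adjacency=adj)


class TestSmallWorld:
    def test_algebraic_identity_and_flag(self):
        g = ring_lattice_with_shortcuts(90, 6, 0.05, seed=2)
        sw = small_world(g, n_random=100, seed=0)
        assert sw.sigma == pytest.approx(sw.gamma / sw.lambda_, abs=1e-12)
        assert sw.sigma > 1.1 and sw.is_small_world

    def test_watts_strogatz_regime_flagged_across_seeds(self):
        for seed in range(5):
            g = ring_lattice_with_shortcuts(90, 6, 0.05, seed=seed)
            assert small_world(g, n_random=50, seed=seed).sigma > 1.1

    def test_dense_random_graph_is_not_small_world(self):
        sigmas = []
        for seed in range(10):
            adj = random_graph_adj(np.random.default_rng(seed), 60, 0.4)
            sigmas.append(small_world(BinaryGraph(adjacency=adj), n_random=50, seed=seed).sigma)
        assert np.all((np.array(sigmas) > 0.8) & (np.array(sigmas) < 1.2))

    def test_deterministic_given_seed(self, rng):
        g = BinaryGraph(adjacency=random_graph_adj(rng, 30, 0.2))
        a = small_world(g, n_random=20, seed=5)
        b = small_world(g, n_random=20, seed=5)
        assert (a.cp_random, a.lp_random) == (b.cp_random, b.lp_random)


class TestAUC:
    def test_constant_and_linear_curves(self):
        schedule = DensitySchedule()
        const = np.full(16, 2.0)
        assert auc_over_densities(const, schedule) == pytest.approx(0.6)
        linear = np.linspace(0, 3, 16)
        assert auc_over_densities(linear, schedule) == pytest.approx(0.45)

    def test_linearity(self, rng):
        schedule = DensitySchedule()
        f = rng.normal(size=16)
        g = rng.normal(size=16)
        lhs = auc_over_densities(2.5 * f - 1.5 * g, schedule)
        rhs = 2.5 * auc_over_densities(f, schedule) - 1.5 * auc_over_densities(g, schedule)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_missing_value_rejected(self):
        values = np.full(16, 1.0)
        values[3] = np.nan
        with pytest.raises(ValueError, match="0.16"):
            auc_over_densities(values, DensitySchedule())


class TestMetricCurves:
    def test_shapes_monotonicity_and_determinism(self, rng):
        m = similarity_matrix(rng, 20)
        curves = metric_curves(m, DensitySchedule(), n_random=0, seed=4, compute_global=False)
        assert set(curves.nodal) == {"degree", "clustering", "path_length", "efficiency"}
        for arr in curves.nodal.values():
            assert arr.shape == (20, 16)
        # nested edge sets make degree curves non-decreasing
        assert np.all(np.diff(curves.nodal["degree"], axis=1) >= 0)
        # global stage on densities where the nulls are not triangle-free
        dense = DensitySchedule(0.26, 0.40, 0.02)
        with_global = metric_curves(m, dense, n_random=10, seed=4)
        assert set(with_global.global_curves) >= {"gamma", "lambda", "sigma"}
        again = metric_curves(m, dense, n_random=10, seed=4)
        np.testing.assert_array_equal(
            with_global.nodal["efficiency"], again.nodal["efficiency"]
        )
        np.testing.assert_array_equal(
            with_global.global_curves["sigma"], again.global_curves["sigma"]
        )

    def test_auc_frame_layout(self, rng):
        curves = metric_curves(
            similarity_matrix(rng, 12), n_random=0, seed=1, compute_global=False
        )
        frame = curves.auc_frame()
        nodal = frame[frame.scope == "node"]
        assert len(nodal) == 12 * 4
        assert set(frame.columns) == {"subject_id", "scope", "region_label", "metric", "auc"}
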
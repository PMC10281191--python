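"""Global graph properties, null normalization, and sparsity AUC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rsnet import graphs, metrics
from rsnet.synthetic import generate_toy_graph

import oracles


class TestNodalProfile:
    def test_complete_graph_fully_clustered(self):
        prof = metrics.nodal_profile(generate_toy_graph("complete", {"n": 5}))
        assert np.all(prof.degree == 4)
        assert np.allclose(prof.clustering, 1.0)
        assert np.allclose(prof.efficiency, 1.0)

    def test_star_has_no_triangles(self):
        prof = metrics.nodal_profile(generate_toy_graph("star", {"n": 5}))
        assert np.allclose(prof.clustering, 0.0)

    def test_clustering_matches_exhaustive_triangle_count(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            adj = rng.random((8, 8)) < 0.4
            adj = np.triu(adj, 1)
            adj = adj | adj.T
            g = graphs.BinaryGraph(adj)
            prof = metrics.nodal_profile(g)
            assert np.allclose(prof.clustering,
                               oracles.clustering_per_node(g.adjacency))


class TestSmallworldBase:
    def test_complete_graph_unit_values(self):
        cp, lp, eg, el = metrics.smallworld_base(generate_toy_graph("complete", {"n": 5}))
        assert (cp, lp, eg, el) == (1.0, 1.0, 1.0, 1.0)

    def test_path_three_hand_counted(self):
        cp, lp, eg, _ = metrics.smallworld_base(generate_toy_graph("path", {"n": 3}))
        assert lp == pytest.approx(4 / 3)
        assert eg == pytest.approx(5 / 6)

    def test_ring_lattice_closed_form_clustering(self):
        # 3(k-2)/(4(k-1)) = 0.5 at k=4
        cp, *_ = metrics.smallworld_base(generate_toy_graph("ring_lattice", {"n": 20, "k": 4}))
        assert cp == pytest.approx(0.5)


class TestAssortativity:
    def test_star_perfectly_disassortative(self):
        for n in (3, 5, 9):
            g = generate_toy_graph("star", {"n": n})
            assert metrics.assortativity(g) == pytest.approx(-1.0)

    def test_regular_graph_undefined(self):
        with pytest.warns(UserWarning, match="regular"):
            r = metrics.assortativity(generate_toy_graph("complete", {"n": 5}))
        assert np.isnan(r)

    def test_matches_edge_list_oracle(self):
        rng = np.random.default_rng(3)
        adj = rng.random((6, 6)) < 0.5
        adj = np.triu(adj, 1)
        adj = adj | adj.T
        g = graphs.BinaryGraph(adj)
        expect = oracles.assortativity_edge_list(g.adjacency)
        if np.isnan(expect):
            return
        assert metrics.assortativity(g) == pytest.approx(expect, abs=1e-12)


class TestHierarchyBeta:
    def test_two_level_regular_union_gives_exact_unity(self):
        # K3 (k=2, C=1) disjoint from a ring lattice (k=4, C=1/2):
        # slope of log C on log k is exactly -1, so beta = 1
        k3 = generate_toy_graph("complete", {"n": 3}).adjacency
        ring = generate_toy_graph("ring_lattice", {"n": 20, "k": 4}).adjacency
        n = 3 + 20
        adj = np.zeros((n, n), dtype=bool)
        adj[:3, :3] = k3
        adj[3:, 3:] = ring
        assert metrics.hierarchy_beta(graphs.BinaryGraph(adj)) == pytest.approx(1.0, abs=1e-9)

    def test_constant_clustering_gives_zero_slope(self):
        # K3 (k=2, C=1) disjoint from K4 (k=3, C=1): flat log-log line
        k3 = generate_toy_graph("complete", {"n": 3}).adjacency
        k4 = generate_toy_graph("complete", {"n": 4}).adjacency
        adj = np.zeros((7, 7), dtype=bool)
        adj[:3, :3] = k3
        adj[3:, 3:] = k4
        assert metrics.hierarchy_beta(graphs.BinaryGraph(adj)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_ols(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            adj = rng.random((8, 8)) < 0.55
            adj = np.triu(adj, 1)
            adj = adj | adj.T
            g = graphs.BinaryGraph(adj)
            expect = oracles.hierarchy_exponent(g.adjacency)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got = metrics.hierarchy_beta(g)
            if np.isnan(expect):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expect, abs=1e-9)

    def test_degenerate_fit_undefined(self):
        with pytest.warns(UserWarning, match="hierarchy undefined"):
            beta = metrics.hierarchy_beta(generate_toy_graph("complete", {"n": 4}))
        assert np.isnan(beta)


class TestSynchronization:
    def test_complete_graph_fully_synchronizable(self):
        # Laplacian of K_n has eigenvalues {0, n, ..., n}
        assert metrics.synchronization(generate_toy_graph("complete", {"n": 5})) == pytest.approx(1.0)

    def test_path_three_hand_eigenvalues(self):
        # L(P3) eigenvalues {0, 1, 3}
        assert metrics.synchronization(generate_toy_graph("path", {"n": 3})) == pytest.approx(1 / 3)

    def test_disconnected_graph_zero(self):
        adj = np.zeros((4, 4), dtype=bool)
        adj[0, 1] = adj[1, 0] = adj[2, 3] = adj[3, 2] = True
        assert metrics.synchronization(graphs.BinaryGraph(adj)) == pytest.approx(0.0)

    def test_edgeless_graph_undefined(self):
        with pytest.warns(UserWarning, match="edgeless"):
            s = metrics.synchronization(graphs.BinaryGraph(np.zeros((3, 3), dtype=bool)))
        assert np.isnan(s)


class TestRewireNull:
    def test_degree_sequence_conserved_and_count(self):
        g = generate_toy_graph("watts_strogatz", {"n": 50, "k": 6, "p": 0.2}, seed=5)
        nulls = metrics.rewire_null(g, n_networks=10, n_swap_factor=10, seed=0)
        assert len(nulls) == 10
        ref = np.sort(g.degrees)
        for h in nulls:
            assert np.array_equal(np.sort(h.degrees), ref)
            assert not h.adjacency.diagonal().any()

    def test_seeded_rewiring_reproducible(self):
        g = generate_toy_graph("erdos_renyi", {"n": 30, "p": 0.3}, seed=1)
        a = metrics.rewire_null(g, 3, 10, seed=42)
        b = metrics.rewire_null(g, 3, 10, seed=42)
        for x, y in zip(a, b):
            assert np.array_equal(x.adjacency, y.adjacency)

    def test_nulls_break_up_triangles(self):
        g = generate_toy_graph("ring_lattice", {"n": 40, "k": 6})
        orig = oracles.triangles_per_node(g.adjacency).sum()
        nulls = metrics.rewire_null(g, 10, 20, seed=3)
        null_tri = np.mean([oracles.triangles_per_node(h.adjacency).sum() for h in nulls])
        assert null_tri < orig


class TestNormalizeSmallworld:
    def test_self_normalization_identity(self):
        g = generate_toy_graph("ring_lattice", {"n": 20, "k": 4})
        gamma, lam, sigma = metrics.normalize_smallworld(g, [g, g, g])
        assert (gamma, lam, sigma) == (1.0, 1.0, 1.0)

    def test_random_graph_is_its_own_null_class(self):
        g = generate_toy_graph("erdos_renyi", {"n": 100, "p": 0.15}, seed=9)
        nulls = metrics.rewire_null(g, 20, 10, seed=2)
        gamma, lam, sigma = metrics.normalize_smallworld(g, nulls)
        assert 0.8 <= gamma <= 1.2
        assert 0.8 <= sigma <= 1.2


class TestCurvesAndAuc:
    def test_constant_curve_scales_with_grid_span(self):
        grid = graphs.sparsity_grid()
        assert metrics.auc(np.full(36, 1.0), grid) == pytest.approx(0.35)
        assert metrics.auc(np.full(36, 3.0), grid) == pytest.approx(1.05)
        assert metrics.auc(np.zeros(36), grid) == 0.0

    def test_linear_curve_exact_integral(self):
        grid = graphs.sparsity_grid()
        assert metrics.auc(grid.copy(), grid) == pytest.approx((0.40**2 - 0.05**2) / 2)

    def test_decreasing_grid_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            metrics.auc(np.ones(3), np.array([0.3, 0.2, 0.1]))

    def test_nan_points_excluded_pairwise(self):
        grid = np.array([0.1, 0.2, 0.3, 0.4])
        vals = np.array([np.nan, 1.0, 1.0, 1.0])
        assert metrics.auc(vals, grid) == pytest.approx(0.2)
        with pytest.raises(ValueError, match="2 defined"):
            metrics.auc(np.array([1.0, np.nan, np.nan, np.nan]), grid)

    def test_curves_cover_all_ten_metrics(self):
        rng = np.random.default_rng(6)
        ts = rng.standard_normal((15, 60))
        cm = graphs.connectivity_matrix(ts)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curves = metrics.metric_curves(
                cm, grid=np.array([0.2, 0.3, 0.4]), n_nulls=5, n_swap_factor=10, seed=0
            )
        assert set(curves) == set(metrics.METRIC_NAMES)
        for c in curves.values():
            assert c.values.shape == (3,)

    @settings(derandomize=True, max_examples=10, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_metrics_invariant_under_node_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        adj = rng.random((10, 10)) < 0.35
        adj = np.triu(adj, 1)
        adj = adj | adj.T
        if adj.sum() < 4:
            return
        perm = rng.permutation(10)
        g1 = graphs.BinaryGraph(adj)
        g2 = graphs.BinaryGraph(adj[np.ix_(perm, perm)])
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for f in (lambda g: metrics.smallworld_base(g)[:3],
                      metrics.assortativity, metrics.synchronization,
                      metrics.hierarchy_beta):
                a, b = f(g1), f(g2)
                assert np.allclose(np.nan_to_num(np.asarray(a, dtype=float)),
                                   np.nan_to_num(np.asarray(b, dtype=float)),
                                   atol=1e-9)
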
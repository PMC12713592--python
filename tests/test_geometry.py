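import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mgw import build_arc_graph, euclidean_arc_graph, geodesic_distances, pullback_metric
from mgw.geometry import ArcGraph, MetricField, knn_edges


def eye_metric(n, k=2):
    return MetricField(np.broadcast_to(np.eye(k), (n, k, k)).copy())


def floyd_warshall_oracle(n, edges, weights):
    """Independent brute-force APSP (triple loop over intermediates)."""
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for (i, j), w in zip(edges, weights):
        D[i, j] = min(D[i, j], w)
        D[j, i] = min(D[j, i], w)
    for k in range(n):
        D = np.minimum(D, D[:, [k]] + D[[k], :])
    return D


def random_connected_graph(n, rng):
    # random spanning tree + extra edges
    edges = [(int(rng.integers(i)), i) for i in range(1, n)]
    extra = rng.integers(0, n, size=(n, 2))
    edges += [(int(a), int(b)) for a, b in extra if a != b]
    edges = np.unique(np.sort(np.asarray(edges), axis=1), axis=0)
    weights = rng.uniform(0.1, 2.0, len(edges))
    return edges, weights


class TestPullbackMetric:
    def test_identity_jacobian(self):
        J = np.broadcast_to(np.eye(2), (4, 2, 2)).copy()
        np.testing.assert_array_equal(pullback_metric(J).g[0], np.eye(2))

    def test_diagonal_jacobian(self):
        J = np.broadcast_to(np.diag([2.0, 1.0]), (3, 2, 2)).copy()
        np.testing.assert_array_equal(pullback_metric(J).g[1], np.diag([4.0, 1.0]))

    def test_zero_jacobian_gives_singular_psd(self):
        g = pullback_metric(np.zeros((5, 3, 2))).g
        np.testing.assert_array_equal(g, np.zeros((5, 2, 2)))
        MetricField(g).validate()  # singular PSD is allowed

    def test_epsilon_regularization(self):
        g = pullback_metric(np.zeros((2, 3, 2)), epsilon=0.5).g
        np.testing.assert_array_equal(g[0], 0.5 * np.eye(2))

    def test_random_jacobian_yields_symmetric_psd(self, rng):
        J = rng.normal(size=(20, 7, 3))
        m = pullback_metric(J)
        m.validate()


class TestArcGraph:
    def test_euclidean_345_edge(self):
        coords = np.array([[0.0, 0.0], [3.0, 4.0], [0.1, 0.1]])
        g = build_arc_graph(coords, eye_metric(3), k_neighbors=2)
        w = dict(zip(map(tuple, g.edges), g.weights))
        assert w[(0, 1)] == pytest.approx(5.0, abs=1e-12)

    def test_mixed_metric_average(self):
        # endpoint metrics diag(4,1) and I with displacement (1,0):
        # w = (sqrt(4) + sqrt(1)) / 2 = 1.5
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 5.0]])
        g = np.stack([np.diag([4.0, 1.0]), np.eye(2), np.eye(2)])
        graph = build_arc_graph(coords, MetricField(g), k_neighbors=1,
                                connect=True)
        w = dict(zip(map(tuple, graph.edges), graph.weights))
        assert w[(0, 1)] == pytest.approx(1.5, abs=1e-14)

    def test_zero_metric_gives_zero_weights(self, rng):
        coords = rng.uniform(size=(10, 2))
        graph = build_arc_graph(coords, MetricField(np.zeros((10, 2, 2))), 3)
        assert np.all(graph.weights == 0)

    def test_k_too_large_rejected(self, rng):
        coords = rng.uniform(size=(5, 2))
        with pytest.raises(ValueError):
            build_arc_graph(coords, eye_metric(5), k_neighbors=5)

    def test_symmetrization_is_union(self):
        # a far point is in nobody's k-NN list, but lists a near point
        coords = np.array([[0.0, 0.0], [0.1, 0.0], [0.2, 0.0], [5.0, 0.0]])
        graph = build_arc_graph(coords, eye_metric(4), k_neighbors=1,
                                connect=False)
        pairs = {tuple(e) for e in graph.edges}
        assert (2, 3) in pairs  # 3 listed 2 even though 2 did not list 3

    def test_bridging_connects_components(self):
        coords = np.vstack([np.random.default_rng(0).uniform(0, 1, (10, 2)),
                            np.random.default_rng(1).uniform(10, 11, (10, 2))])
        g = build_arc_graph(coords, eye_metric(20), k_neighbors=3, connect=True)
        assert g.connected
        D = geodesic_distances(g)
        assert np.isfinite(D).all()

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_identity_arc_weights_equal_euclidean_bitwise(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(size=(30, 2))
        ga = build_arc_graph(coords, eye_metric(30), 5)
        ge = euclidean_arc_graph(coords, 5)
        assert np.array_equal(ga.edges, ge.edges)
        assert np.array_equal(ga.weights, ge.weights)  # bitwise


class TestGeodesics:
    def test_three_vertex_path(self):
        g = ArcGraph(3, np.array([[0, 1], [1, 2]]), np.array([1.0, 2.0]), True)
        D = geodesic_distances(g)
        assert D[0, 2] == 3.0
        assert D[2, 0] == 3.0
        assert np.all(np.diag(D) == 0)

    def test_matches_floyd_warshall_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(5, 51))
            edges, weights = random_connected_graph(n, rng)
            D = geodesic_distances(ArcGraph(n, edges, weights, True))
            Dref = floyd_warshall_oracle(n, edges, weights)
            np.testing.assert_allclose(D, Dref, atol=1e-12)

    def test_grid_geodesics_dominate_euclidean(self):
        ax = np.linspace(0, 1, 8)
        coords = np.column_stack([g.ravel() for g in np.meshgrid(ax, ax)])
        graph = build_arc_graph(coords, eye_metric(64), k_neighbors=8)
        D = geodesic_distances(graph)
        E = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        assert (D >= E - 1e-12).all()
        # equality on axis-aligned neighbors
        assert D[0, 1] == pytest.approx(E[0, 1], abs=1e-14)
        assert D[0, 8] == pytest.approx(E[0, 8], abs=1e-14)

    def test_adding_edges_never_increases_distances(self):
        rng = np.random.default_rng(3)
        n = 30
        edges, weights = random_connected_graph(n, rng)
        D1 = geodesic_distances(ArcGraph(n, edges, weights, True))
        extra = np.array([[0, n - 1], [1, n - 2]])
        ew = rng.uniform(0.05, 0.5, 2)
        D2 = geodesic_distances(ArcGraph(
            n, np.vstack([edges, extra]), np.concatenate([weights, ew]), True))
        assert (D2 <= D1 + 1e-12).all()

    def test_disconnected_reports_component_sizes(self):
        g = ArcGraph(4, np.array([[0, 1], [2, 3]]), np.ones(2), False)
        with pytest.raises(ValueError, match=r"component sizes \[2, 2\]"):
            geodesic_distances(g)

    def test_symmetry_and_triangle_inequality(self, rng):
        coords = rng.uniform(size=(40, 2))
        J = rng.normal(size=(40, 6, 2))
        graph = build_arc_graph(coords, pullback_metric(J), 6)
        D = geodesic_distances(graph)
        np.testing.assert_allclose(D, D.T, atol=1e-10)
        # triangle inequality of the graph metric
        viol = (D[:, None, :] + D[None, :, :]).min(axis=1) - D
        assert viol.min() > -1e-10


class TestKnnEdges:
    def test_edge_count_and_uniqueness(self, rng):
        coords = rng.uniform(size=(25, 2))
        e = knn_edges(coords, 4)
        assert (e[:, 0] < e[:, 1]).all()
        assert len(np.unique(e, axis=0)) == len(e)
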
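"""Graph primitives: Laplacians, component counting, simplex projection and
the adaptive-neighbor initial graph."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from lrcmc import (
    AffinityGraph,
    ViewData,
    build_laplacian,
    connected_components,
    count_zero_eigenvalues,
    init_affinity,
    project_capped_simplex,
)

from oracles import brute_simplex_projection, random_affinity, slsqp_column_qp


def graph_of(w, k=None):
    return AffinityGraph(weights=np.asarray(w, dtype=float), k=k)


class TestBuildLaplacian:
    def test_single_edge_closed_form(self):
        lap = build_laplacian(graph_of([[0, 1], [1, 0]]))
        np.testing.assert_allclose(lap.matrix, [[1, -1], [-1, 1]])
        np.testing.assert_allclose(
            np.linalg.eigvalsh(lap.matrix), [0.0, 2.0], atol=1e-12
        )

    def test_empty_graph_is_zero_matrix(self):
        lap = build_laplacian(graph_of(np.zeros((3, 3))))
        assert np.all(lap.matrix == 0)
        assert np.all(lap.degree == 0)

    def test_asymmetric_input_symmetrized(self):
        asym = build_laplacian(graph_of([[0, 1], [0, 0]]))
        sym = build_laplacian(graph_of([[0, 0.5], [0.5, 0]]))
        np.testing.assert_allclose(asym.matrix, sym.matrix)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            build_laplacian(graph_of([[0, -1], [1, 0]]))

    def test_row_sums_zero_and_psd(self, rng):
        w = random_affinity(rng, 15)
        lap = build_laplacian(graph_of(w))
        np.testing.assert_allclose(lap.matrix.sum(axis=1), 0.0, atol=1e-10)
        assert np.linalg.eigvalsh(lap.matrix).min() > -1e-10


class TestComponentCounting:
    def test_two_disjoint_edges(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = w[2, 3] = w[3, 2] = 1.0
        assert count_zero_eigenvalues(build_laplacian(graph_of(w))) == 2

    def test_path_graph_connected(self):
        w = np.zeros((4, 4))
        for i in range(3):
            w[i, i + 1] = w[i + 1, i] = 1.0
        assert count_zero_eigenvalues(build_laplacian(graph_of(w))) == 1

    def test_non_finite_rejected(self):
        lap = build_laplacian(graph_of(np.zeros((2, 2))))
        lap.matrix[0, 0] = np.nan
        with pytest.raises(ValueError):
            count_zero_eigenvalues(lap)

    def test_knn_graph_on_three_clusters(self, rng):
        # three separated point clouds; small-k neighbor graph must have
        # 3 components by both routes
        x = np.concatenate(
            [rng.normal(c, 0.05, size=(10, 2)) for c in (0.0, 50.0, 100.0)]
        )
        view = ViewData(matrix=x.T)
        g = init_affinity(view, k=3)
        count, _ = connected_components(g)
        assert count == 3
        assert count_zero_eigenvalues(build_laplacian(g)) == 3

    def test_zero_graph_all_singletons(self):
        count, labels = connected_components(graph_of(np.zeros((5, 5))))
        assert count == 5
        assert list(labels) == [0, 1, 2, 3, 4]

    def test_two_cliques(self):
        w = np.zeros((5, 5))
        w[np.ix_([0, 1, 2], [0, 1, 2])] = 1.0
        w[np.ix_([3, 4], [3, 4])] = 1.0
        np.fill_diagonal(w, 0.0)
        count, labels = connected_components(graph_of(w))
        assert count == 2
        assert sorted(np.bincount(labels)) == [2, 3]
        assert count_zero_eigenvalues(build_laplacian(graph_of(w))) == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_eigencount_equals_traversal(self, seed):
        # zero-eigenvalue multiplicity == graph-traversal component count
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 31))
        w = random_affinity(rng, n)
        # randomly disconnect blocks
        cut = int(rng.integers(1, n))
        w[:cut, cut:] = 0.0
        w[cut:, :cut] = 0.0
        w = w / np.maximum(w.sum(axis=0, keepdims=True), 1e-12)
        g = graph_of(w)
        count, _ = connected_components(g)
        assert count_zero_eigenvalues(build_laplacian(g), tol=1e-8) == count


class TestSimplexProjection:
    def test_feasible_point_unchanged(self):
        v = np.array([0.2, 0.0, 0.5, 0.3])
        np.testing.assert_allclose(
            project_capped_simplex(v, forbidden_index=1), v, atol=1e-12
        )

    def test_dominant_coordinate(self):
        out = project_capped_simplex(np.array([10.0, 0.0, 0.0]), forbidden_index=2)
        np.testing.assert_allclose(out, [1.0, 0.0, 0.0], atol=1e-12)

    def test_infeasible_single_coordinate(self):
        with pytest.raises(ValueError):
            project_capped_simplex(np.array([1.0]), forbidden_index=0)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            project_capped_simplex(np.array([np.inf, 0.0]))

    @given(
        hnp.arrays(
            np.float64,
            st.integers(2, 8),
            elements=st.floats(-5, 5, allow_nan=False),
        ),
        st.integers(0, 7),
    )
    def test_output_on_simplex(self, v, fidx):
        fidx = fidx % v.size
        out = project_capped_simplex(v, forbidden_index=fidx)
        assert out.min() >= 0.0
        assert out[fidx] == 0.0
        assert abs(out.sum() - 1.0) < 1e-9

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_kkt_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        v = rng.normal(0, 2, size=n)
        fidx = int(rng.integers(0, n))
        ours = project_capped_simplex(v, forbidden_index=fidx)
        ref = brute_simplex_projection(v, forbidden=fidx)
        np.testing.assert_allclose(ours, ref, atol=1e-9)


class TestInitAffinity:
    def test_one_dimensional_worked_example(self):
        # points {0,1,3,10}, column for point 0, k=2:
        # distances (1, 9, 100) -> weights (99/190, 91/190, 0)
        view = ViewData(matrix=np.array([[0.0, 1.0, 3.0, 10.0]]))
        g = init_affinity(view, k=2)
        np.testing.assert_allclose(
            g.weights[:, 0], [0.0, 99 / 190, 91 / 190, 0.0], atol=1e-12
        )
        g.validate()

    def test_k_equals_one_gives_unit_weight(self, rng):
        view = ViewData(matrix=rng.normal(size=(3, 6)))
        g = init_affinity(view, k=1)
        assert np.all((g.weights > 0).sum(axis=0) == 1)
        np.testing.assert_allclose(g.weights.sum(axis=0), 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_each_column_matches_qp_oracle(self, seed):
        # with the implicit per-column ridge, each column solves
        # min sum_i d_i s_i + alpha ||s||^2 on the zero-diagonal simplex
        rng = np.random.default_rng(seed)
        view = ViewData(matrix=rng.normal(size=(3, 8)))
        g, alphas = init_affinity(view, k=3, return_alpha=True)
        x = view.matrix.T
        for j in range(8):
            d = np.sum((x - x[j]) ** 2, axis=1)
            ref = slsqp_column_qp(2.0 * alphas[j], d, j)
            np.testing.assert_allclose(g.weights[:, j], ref, atol=1e-6)

    def test_rotation_invariance(self, rng):
        x = rng.normal(size=(4, 10))
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        g1 = init_affinity(ViewData(matrix=x), k=3)
        g2 = init_affinity(ViewData(matrix=q @ x), k=3)
        np.testing.assert_allclose(g1.weights, g2.weights, atol=1e-8)

    def test_duplicate_points_get_uniform_tied_weights(self):
        x = np.array([[0.0, 0.0, 0.0, 0.0, 5.0, 6.0]])
        g = init_affinity(ViewData(matrix=x), k=2)
        # column 0 sees three coincident points beyond its budget of 2
        np.testing.assert_allclose(
            g.weights[1:4, 0], [1 / 3, 1 / 3, 1 / 3], atol=1e-12
        )

    def test_equidistant_fallback_warns(self):
        # a regular simplex: every distance equal -> zero denominator
        x = np.eye(4).T
        with pytest.warns(RuntimeWarning):
            g = init_affinity(ViewData(matrix=x), k=2)
        np.testing.assert_allclose(g.weights.sum(axis=0), 1.0)

    @pytest.mark.parametrize("k", [0, 99])
    def test_bad_neighbor_count_rejected(self, rng, k):
        view = ViewData(matrix=rng.normal(size=(2, 6)))
        with pytest.raises(ValueError):
            init_affinity(view, k=k)

    def test_invariants_on_random_input(self, rng):
        view = ViewData(matrix=rng.normal(size=(5, 20)))
        g = init_affinity(view, k=4)
        g.validate()
        assert np.all((g.weights > 0).sum(axis=0) == 4)
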
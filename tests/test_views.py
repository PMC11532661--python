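import numpy as np
import pytest

from oracles import dm_affinity_loop, pairwise_distances_loop, topk_rows_loop
from scmvcc import (
    AffinityGraph,
    DegenerateInputError,
    apply_glf,
    assemble_views,
    build_dm_adjacency,
    build_knn_adjacency,
    dm_affinity,
    normalized_laplacian_filter,
    pairwise_distances,
)
from scmvcc.views import DistanceMatrix


def graph_from(a, method="knn", k=1):
    return AffinityGraph(a=np.asarray(a, float), method=method, k=k)


class TestPairwiseDistances:
    def test_three_four_five(self):
        d = pairwise_distances(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert d.d[0, 1] == pytest.approx(5.0)

    def test_duplicate_cells_have_zero_distance(self):
        d = pairwise_distances(np.array([[1.0, 2.0], [1.0, 2.0], [0.0, 0.0]]))
        assert d.d[0, 1] == 0.0

    def test_matches_double_loop(self, rng):
        x = rng.normal(size=(8, 5))
        d = pairwise_distances(x)
        np.testing.assert_allclose(d.d, pairwise_distances_loop(x), atol=1e-9)

    def test_single_cell_rejected(self):
        with pytest.raises(DegenerateInputError):
            pairwise_distances(np.ones((1, 3)))


class TestKnnAdjacency:
    def test_collinear_hand_case(self):
        pts = np.array([[0.0], [1.0], [2.0], [10.0]])
        d = pairwise_distances(pts)
        g = build_knn_adjacency(d, k=1)
        # directed picks: 0->1, 1->0 (tie with 2 broken to lower index), 2->1, 3->2
        expected = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 2), (2, 3)]:
            expected[i, j] = expected[j, i] = 1
        expected[1, 2] = expected[2, 1] = 1
        np.testing.assert_array_equal(g.a, expected)

    def test_k_max_gives_complete_graph(self, rng):
        d = pairwise_distances(rng.normal(size=(6, 3)))
        g = build_knn_adjacency(d, k=5)
        np.testing.assert_array_equal(g.a, 1 - np.eye(6))

    def test_directed_rows_sum_to_k_and_union_matches_sort_oracle(self, rng):
        x = rng.normal(size=(12, 4))
        d = pairwise_distances(x)
        scores = d.d.copy()
        np.fill_diagonal(scores, np.inf)
        directed = topk_rows_loop(d.d, 3, largest=False)
        assert (directed.sum(axis=1) == 3).all()
        g = build_knn_adjacency(d, k=3)
        np.testing.assert_array_equal(g.a, np.maximum(directed, directed.T))

    def test_min_degree_at_least_k(self, rng):
        d = pairwise_distances(rng.normal(size=(15, 3)))
        g = build_knn_adjacency(d, k=4)
        assert g.a.sum(axis=1).min() >= 4

    def test_k_out_of_range(self, rng):
        d = pairwise_distances(rng.normal(size=(5, 2)))
        with pytest.raises(ValueError):
            build_knn_adjacency(d, k=5)

    def test_permutation_equivariance(self, rng):
        x = rng.normal(size=(10, 4))
        d = pairwise_distances(x)
        perm = rng.permutation(10)
        d_perm = DistanceMatrix(d.d[np.ix_(perm, perm)])
        g = build_knn_adjacency(d, k=3)
        g_perm = build_knn_adjacency(d_perm, k=3)
        np.testing.assert_array_equal(g_perm.a, g.a[np.ix_(perm, perm)])


class TestDmAffinity:
    def test_unit_diagonal(self, rng):
        d = pairwise_distances(rng.normal(size=(7, 3)))
        aff = dm_affinity(d, k_bw=3)
        np.testing.assert_array_equal(np.diag(aff), 1.0)

    def test_two_cell_closed_form(self):
        # cells 0 and 1 each have a helper neighbour at distance sigma, so
        # both bandwidths are sigma and d01 = 2 sigma^2 gives exp(-1)
        sigma = 1.7
        d01 = 2 * sigma**2
        far = 50.0
        d = np.array(
            [
                [0.0, d01, sigma, far],
                [d01, 0.0, far, sigma],
                [sigma, far, 0.0, far],
                [far, sigma, far, 0.0],
            ]
        )
        aff = dm_affinity(DistanceMatrix(d), k_bw=1)
        assert aff[0, 1] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_matches_per_pair_loop(self, rng):
        d = pairwise_distances(rng.normal(size=(10, 6)))
        aff = dm_affinity(d, k_bw=3)
        np.testing.assert_allclose(aff, dm_affinity_loop(d.d, 3), atol=1e-12)

    def test_values_in_unit_interval(self, rng):
        d = pairwise_distances(rng.normal(size=(9, 4)))
        aff = dm_affinity(d, k_bw=2)
        assert (aff > 0).all() and (aff <= 1).all()

    def test_duplicate_points_floor_bandwidth(self, rng):
        x = rng.normal(size=(6, 3))
        x[1] = x[0]
        d = pairwise_distances(x)
        aff = dm_affinity(d, k_bw=1)
        assert np.isfinite(aff).all()

    def test_squared_distance_variant(self, rng):
        d = pairwise_distances(rng.normal(size=(8, 3)))
        aff_lin = dm_affinity(d, k_bw=3, squared_distance=False)
        aff_sq = dm_affinity(d, k_bw=3, squared_distance=True)
        assert not np.allclose(aff_lin, aff_sq)


class TestDmAdjacency:
    def test_unique_argmax_selected(self):
        aff = np.eye(3)
        aff[0, 1] = aff[1, 0] = 0.9
        aff[0, 2] = aff[2, 0] = 0.1
        aff[1, 2] = aff[2, 1] = 0.2
        g = build_dm_adjacency(aff, k=1)
        assert g.a[0, 1] == 1 and g.a[1, 0] == 1

    def test_all_equal_ties_pick_lowest_indices(self):
        aff = np.full((5, 5), 0.4)
        np.fill_diagonal(aff, 1.0)
        g = build_dm_adjacency(aff, k=2)
        directed_expect = topk_rows_loop(aff, 2, largest=True)
        np.testing.assert_array_equal(g.a, np.maximum(directed_expect, directed_expect.T))
        assert g.a[0, 1] == 1 and g.a[0, 2] == 1

    def test_matches_full_sort_oracle(self, rng):
        d = pairwise_distances(rng.normal(size=(10, 5)))
        aff = dm_affinity(d, k_bw=3)
        g = build_dm_adjacency(aff, k=3)
        directed = topk_rows_loop(aff, 3, largest=True)
        np.testing.assert_array_equal(g.a, np.maximum(directed, directed.T))

    def test_dm_graph_denser_on_heterogeneous_density_data(self, rng):
        # one tight and one diffuse cluster: the adaptive bandwidth links
        # across density regimes, so the union graph carries more edges
        tight = rng.normal(scale=0.05, size=(20, 3))
        loose = rng.normal(scale=2.0, size=(20, 3)) + 8.0
        x = np.vstack([tight, loose])
        d = pairwise_distances(x)
        k = 5
        g_knn = build_knn_adjacency(d, k=k)
        g_dm = build_dm_adjacency(dm_affinity(d, k_bw=k), k=k)
        assert g_dm.n_edges() >= g_knn.n_edges()


class TestGraphFilter:
    def test_edgeless_graph_is_identity(self):
        g = graph_from(np.zeros((4, 4)))
        h = normalized_laplacian_filter(g)
        np.testing.assert_array_equal(h.h, np.eye(4))

    def test_two_node_single_edge(self):
        g = graph_from([[0, 1], [1, 0]])
        h = normalized_laplacian_filter(g)
        np.testing.assert_allclose(h.h, [[0.5, 0.5], [0.5, 0.5]], atol=1e-15)

    def test_spectrum_in_unit_interval(self, rng):
        a = (rng.random((9, 9)) < 0.4).astype(float)
        a = np.maximum(a, a.T)
        np.fill_diagonal(a, 0)
        h = normalized_laplacian_filter(graph_from(a))
        eig = np.linalg.eigvalsh(h.h)
        assert eig.max() == pytest.approx(1.0, abs=1e-8)
        assert eig.min() >= -1.0 - 1e-8


class TestApplyGlf:
    def test_identity_filter_preserves_features(self, rng):
        h = normalized_laplacian_filter(graph_from(np.zeros((5, 5))))
        x = rng.normal(size=(5, 3))
        np.testing.assert_array_equal(apply_glf(h, x, t=3), x)

    def test_associativity(self, rng):
        a = (rng.random((6, 6)) < 0.5).astype(float)
        a = np.maximum(a, a.T)
        np.fill_diagonal(a, 0)
        h = normalized_laplacian_filter(graph_from(a))
        x = rng.normal(size=(6, 4))
        np.testing.assert_allclose(apply_glf(h, x, t=2), (h.h @ h.h) @ x, atol=1e-9)

    def test_spectral_contraction(self, rng):
        a = (rng.random((8, 8)) < 0.4).astype(float)
        a = np.maximum(a, a.T)
        np.fill_diagonal(a, 0)
        h = normalized_laplacian_filter(graph_from(a))
        for _ in range(5):
            v = rng.normal(size=(8, 1))
            v /= np.linalg.norm(v)
            assert np.linalg.norm(apply_glf(h, v, t=3)) <= 1.0 + 1e-12

    def test_depth_zero_rejected(self, rng):
        h = normalized_laplacian_filter(graph_from(np.zeros((3, 3))))
        with pytest.raises(ValueError):
            apply_glf(h, np.ones((3, 2)), t=0)


class TestAssembleViews:
    def test_edgeless_graphs_carry_raw_features(self, rng):
        x = rng.normal(size=(5, 4))
        gk = graph_from(np.zeros((5, 5)), "knn")
        gd = graph_from(np.zeros((5, 5)), "dm")
        bundle = assemble_views(gk, gd, x, t=2)
        for _, f in bundle.views:
            np.testing.assert_array_equal(f, x)

    def test_identical_graphs_collapse_features(self, rng):
        a = np.zeros((6, 6))
        a[0, 1] = a[1, 0] = 1
        x = rng.normal(size=(6, 3))
        bundle = assemble_views(graph_from(a, "knn"), graph_from(a, "dm"), x, t=2)
        ref = bundle.views[0][1]
        for _, f in bundle.views[1:]:
            np.testing.assert_allclose(f, ref)

    def test_feature_sharing_pattern(self, small_bundle):
        bundle, _ = small_bundle
        f1, f2, f3, f4 = (f for _, f in bundle.views)
        np.testing.assert_array_equal(f1, f3)  # F_knn shared by G1, G3
        np.testing.assert_array_equal(f2, f4)  # F_dm shared by G2, G4
        assert not np.array_equal(f1, f2)

    def test_group_structure(self, small_bundle):
        bundle, _ = small_bundle
        assert bundle.GROUPS == ((0, 1), (2, 3))
        np.testing.assert_array_equal(bundle.views[0][0].a, bundle.views[1][0].a)
        np.testing.assert_array_equal(bundle.views[2][0].a, bundle.views[3][0].a)


class TestGraphExport:
    def test_edge_list_tsv(self, rng, tmp_path):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 1
        a[2, 3] = a[3, 2] = 1
        g = graph_from(a)
        path = tmp_path / "edges.tsv"
        g.to_edge_list(path)
        lines = path.read_text().strip().splitlines()
        assert lines == ["source\ttarget", "0\t1", "2\t3"]
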
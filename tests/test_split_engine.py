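import numpy as np
import pytest
from sklearn.metrics import calinski_harabasz_score

from appcluster import (
    APPConfig,
    adjusted_rand,
    app_cluster,
    calinski_harabasz_2d,
    candidates_for_projection,
    split_assignment,
)
from appcluster.boundary_search import BoundaryPath
from appcluster import synthetic_data as syn

from conftest import grid_from_points


class TestCalinskiHarabasz:
    def test_worked_four_point_example(self):
        pts = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
        below = np.array([True, True, False, False])
        # B = 100, W = 1, CH = (100/1)/(1/2) = 200
        assert calinski_harabasz_2d(pts, below) == pytest.approx(200.0)

    def test_matches_sklearn_oracle(self):
        """Agreement with an independent implementation to 1e-9 on 100
        seeded 2-cluster instances."""
        rng = np.random.default_rng(77)
        for _ in range(100):
            n = int(rng.integers(6, 60))
            pts = rng.normal(size=(n, 2))
            below = rng.random(n) < 0.5
            if below.all() or (~below).all():
                below[0] = not below[0]
            ours = calinski_harabasz_2d(pts, below)
            ref = calinski_harabasz_score(pts, below.astype(int))
            assert ours == pytest.approx(ref, abs=1e-9, rel=1e-9)

    def test_zero_within_dispersion_is_infinite(self):
        pts = np.array([[0.0, 0.0]] * 3 + [[5.0, 5.0]] * 3)
        below = np.array([True] * 3 + [False] * 3)
        assert np.isinf(calinski_harabasz_2d(pts, below))

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(40, 2))
        below = rng.random(40) < 0.4
        below[0], below[1] = True, False
        a = calinski_harabasz_2d(pts, below)
        b = calinski_harabasz_2d(pts * 7.3, below)
        assert a == pytest.approx(b, rel=1e-12)


class TestSplitAssignment:
    def test_flat_boundary(self):
        from appcluster.density_grid import UnitSquareProjection

        coords = np.array([[0.1, 0.2], [0.9, 0.8], [0.5, 0.45]])
        proj = UnitSquareProjection(0, 1, 0, 1, 0, 1, coords)
        N = 10
        path = BoundaryPath(rows=np.full(N, 4), q=0.5, action=0.0)  # centers 0.45
        below = split_assignment(proj, path)
        # y=0.2 below, y=0.8 above, y=0.45 exactly on the boundary -> below
        assert below.tolist() == [True, False, True]
        assert below.sum() + (~below).sum() == 3


class TestCandidatesForProjection:
    def test_two_blobs_split_with_correct_sizes(self, two_blob_vertical):
        X, y = two_blob_vertical
        rec = candidates_for_projection(
            X, np.arange(len(X)), 0, 1, APPConfig(min_cluster_size=50)
        )
        assert rec is not None
        sizes = sorted([len(rec.below_idx), len(rec.above_idx)])
        assert sizes == [200, 200]
        lab_below = set(y[rec.below_idx])
        assert lab_below in ({0}, {1})

    def test_identical_points_degenerate(self):
        X = np.ones((100, 2))
        rec = candidates_for_projection(X, np.arange(100), 0, 1, APPConfig(min_cluster_size=5))
        assert rec is None

    def test_size_filter_blocks_split(self, two_blob_vertical):
        X, _ = two_blob_vertical  # 200 events per blob
        rec = candidates_for_projection(
            X, np.arange(len(X)), 0, 1, APPConfig(min_cluster_size=250)
        )
        assert rec is None


class TestAppCluster:
    def test_stop_rule_below_twice_min_size(self):
        rng = np.random.default_rng(0)
        mcs = 50
        X = rng.normal(size=(2 * mcs - 1, 3))
        tree, labels = app_cluster(X, APPConfig(min_cluster_size=mcs))
        assert tree.n_clusters == 1
        assert set(labels) == {0}

    def test_two_blobs_perfect_recovery(self):
        spec = syn.MixtureSpec(
            components=(
                syn.Component((0.0, 0.0, 0.0), (1.0, 1.0, 1.0), 0.5),
                syn.Component((10.0, 0.0, 0.0), (1.0, 1.0, 1.0), 0.5),
            ),
            n_total=400,
            seed=3,
        )
        X, y = syn.make_blobs(spec)
        tree, labels = app_cluster(X, APPConfig(min_cluster_size=50))
        assert tree.n_clusters == 2
        assert adjusted_rand(labels, y) == 1.0

    def test_four_blobs_exact_leaves(self, four_blob_data):
        X, y = four_blob_data
        tree, labels = app_cluster(X, APPConfig(min_cluster_size=50))
        assert tree.n_clusters == 4
        assert adjusted_rand(labels, y) >= 0.99

    def test_labels_partition_and_leaf_sizes(self, four_blob_data):
        X, _ = four_blob_data
        mcs = 50
        tree, labels = app_cluster(X, APPConfig(min_cluster_size=mcs))
        assert len(labels) == len(X)
        ids = np.unique(labels)
        assert ids.tolist() == list(range(len(ids)))  # contiguous from 0
        assert np.bincount(labels).min() >= mcs
        assert tree.n_clusters <= len(X) // mcs

    def test_unstructured_data_leaf_invariants(self):
        """On structureless data any splits found must still respect the
        minimum size and partition rules."""
        rng = np.random.default_rng(8)
        X = rng.normal(size=(400, 3))
        mcs = 40
        tree, labels = app_cluster(X, APPConfig(min_cluster_size=mcs))
        assert np.bincount(labels).min() >= mcs
        assert np.bincount(labels).sum() == 400

    def test_column_permutation_equivariance(self, four_blob_data):
        X, _ = four_blob_data
        perm = [2, 0, 1]
        _, labels_a = app_cluster(X, APPConfig(min_cluster_size=50))
        _, labels_b = app_cluster(X[:, perm], APPConfig(min_cluster_size=50))
        assert adjusted_rand(labels_a, labels_b) == 1.0

    def test_determinism_across_runs_and_workers(self, four_blob_data):
        X, _ = four_blob_data
        _, l1 = app_cluster(X, APPConfig(min_cluster_size=50, n_jobs=1))
        _, l2 = app_cluster(X, APPConfig(min_cluster_size=50, n_jobs=1))
        _, l3 = app_cluster(X, APPConfig(min_cluster_size=50, n_jobs=2))
        assert np.array_equal(l1, l2)
        assert np.array_equal(l1, l3)

    def test_smaller_min_size_never_coarsens(self, four_blob_data):
        X, _ = four_blob_data
        tree_big, _ = app_cluster(X, APPConfig(min_cluster_size=200))
        tree_small, _ = app_cluster(X, APPConfig(min_cluster_size=50))
        assert tree_small.n_clusters >= tree_big.n_clusters

    def test_input_validation(self):
        with pytest.raises(ValueError):
            app_cluster(np.ones((10, 1)), APPConfig(min_cluster_size=2))
        X = np.ones((10, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            app_cluster(X, APPConfig(min_cluster_size=2))

    def test_tree_report_roundtrip(self, four_blob_data):
        X, _ = four_blob_data
        tree, labels = app_cluster(X, APPConfig(min_cluster_size=50))
        d = tree.to_dict()
        assert d["n_events"] == len(X)

        def leaf_sizes(node):
            if node["leaf"]:
                return [node["size"]]
            return leaf_sizes(node["below"]) + leaf_sizes(node["above"])

        assert sorted(leaf_sizes(d["tree"])) == sorted(np.bincount(labels).tolist())
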
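"""PCA reduction, k-means, hybrid k-means->Ward, elbow, semantic ordering."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.datasets import make_blobs
from sklearn.metrics import adjusted_rand_score

from coroclust.clustering import (hybrid_cluster, kmeans_cluster,
                                  order_clusters_semantic, pca_reduce,
                                  select_k_elbow, total_wcss, ward_merge,
                                  ClusterLabeling)


class TestPCAReduce:
    def test_line_in_high_dim_gives_one_component(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=(500, 1))
        direction = rng.normal(size=(1, 20))
        x = t @ direction + 5.0
        red = pca_reduce(x + rng.normal(scale=1e-9, size=x.shape))
        assert red.n_components == 1
        assert red.explained_variance_fractions[0] == pytest.approx(1.0, abs=1e-6)

    def test_isotropic_gaussian_three_components(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10_000, 3))
        red = pca_reduce(x)
        assert red.n_components == 3
        np.testing.assert_allclose(red.explained_variance_fractions, 1 / 3,
                                   atol=0.02)

    def test_full_variance_keeps_rank(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(100, 4))
        x = np.hstack([x, x[:, :2]])  # rank 4 in 6 columns
        red = pca_reduce(x, variance_fraction=1.0)
        assert red.n_components == 4

    def test_constant_columns_dropped(self):
        rng = np.random.default_rng(3)
        x = np.hstack([rng.normal(size=(50, 3)), np.full((50, 1), 7.0)])
        red = pca_reduce(x)
        assert red.dropped_constant == ["f3"]

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="2 rows"):
            pca_reduce(np.zeros((1, 5)))

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pca_reduce(np.ones((10, 3)))


class TestKMeans:
    def test_k1_single_cluster(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(50, 3))
        cl = kmeans_cluster(x, 1, seed=0)
        assert set(cl.labels) == {0}
        np.testing.assert_allclose(cl.centroids[0], x.mean(axis=0), atol=1e-9)

    def test_separated_blobs_perfect_recovery(self):
        x, y = make_blobs(n_samples=600, centers=3, cluster_std=0.5,
                          center_box=(-30, 30), random_state=0)
        cl = kmeans_cluster(x, 3, seed=0)
        assert adjusted_rand_score(y, cl.labels) == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(300, 5))
        a = kmeans_cluster(x, 4, seed=9)
        b = kmeans_cluster(x, 4, seed=9)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_k_exceeding_rows_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_cluster(np.zeros((5, 2)), 6, seed=0)


class TestHybrid:
    def test_reduction_case_matches_scipy_ward(self):
        """k_pre = n (every point its own preliminary cluster) must equal
        plain Ward agglomeration of the points (scipy as oracle)."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=(60, 4))
        cl = hybrid_cluster(x, k_pre=60, k_final=4, seed=0)
        z = linkage(x, method="ward")
        oracle = fcluster(z, t=4, criterion="maxclust")
        assert adjusted_rand_score(oracle, cl.labels) == 1.0

    FIVE_CENTERS = np.array([[0, 0], [20, 0], [0, 20], [20, 20], [40, 10]],
                            dtype=float)

    @pytest.mark.parametrize("seed", range(1, 11))
    def test_five_blobs_perfect_recovery(self, seed):
        x, y = make_blobs(n_samples=1000, centers=self.FIVE_CENTERS,
                          cluster_std=0.5, random_state=seed)
        cl = hybrid_cluster(x, k_pre=50, k_final=5, seed=seed)
        assert adjusted_rand_score(y, cl.labels) == 1.0

    def test_ward_stage_beats_random_merges(self):
        rng = np.random.default_rng(7)
        x, _ = make_blobs(n_samples=800, centers=5, cluster_std=2.0,
                          random_state=3)
        cl = hybrid_cluster(x, k_pre=50, k_final=5, seed=3)
        w_hybrid = total_wcss(x, cl.labels)
        pre = kmeans_cluster(x, 50, seed=3)
        for _ in range(10):
            collapse = rng.integers(0, 5, size=50)
            w_rand = total_wcss(x, collapse[pre.labels])
            assert w_hybrid <= w_rand + 1e-6

    def test_k_final_greater_than_k_pre_rejected(self):
        with pytest.raises(ValueError):
            hybrid_cluster(np.zeros((30, 2)), k_pre=5, k_final=6, seed=0)

    def test_ward_merge_size_weighting(self):
        # two near centroids with tiny masses merge before two distant
        # heavy ones: cost n_a n_b / (n_a + n_b) ||c_a - c_b||^2
        cents = np.array([[0.0], [1.0], [10.0], [10.8]])
        sizes = np.array([1000.0, 1000.0, 1.0, 1.0])
        group = ward_merge(cents, sizes, 3)
        assert group[2] == group[3]
        assert group[0] != group[1]


class TestElbow:
    def test_three_blobs_selects_three(self):
        x, _ = make_blobs(n_samples=900, centers=3, cluster_std=0.5,
                          center_box=(-30, 30), random_state=1)
        k, wcss = select_k_elbow(x, seed=1)
        assert k == 3

    def test_single_blob_valid_range(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(500, 3))
        k, _ = select_k_elbow(x, seed=8)
        assert 3 <= k <= 9

    def test_wcss_nonincreasing(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(400, 4))
        _, wcss = select_k_elbow(x, seed=9)
        vals = [wcss[k] for k in sorted(wcss)]
        diffs = np.diff(vals)
        # allow tiny local-optimum noise relative to curve scale
        assert np.all(diffs <= 0.01 * vals[0])

    def test_no_interior_point_rejected(self):
        with pytest.raises(ValueError, match="interior"):
            select_k_elbow(np.zeros((50, 2)) + np.random.default_rng(0).normal(size=(50, 2)),
                           k_min=2, k_max=3, seed=0)


def _toy_table(n=60):
    rng = np.random.default_rng(0)
    return pd.DataFrame({
        "mean": np.concatenate([rng.normal(650, 10, 20),
                                rng.normal(300, 10, 20),
                                rng.normal(250, 10, 20)]),
        "local_radius_mm": np.concatenate([rng.normal(1.5, 0.05, 20),
                                           rng.normal(2.0, 0.05, 20),
                                           rng.normal(1.0, 0.05, 20)]),
    })


class TestSemanticOrdering:
    def test_calcified_and_width_ranks(self):
        table = _toy_table()
        labels = np.repeat([0, 1, 2], 20)
        cl = ClusterLabeling(labels=labels, k=3, centroids=np.zeros((3, 2)),
                             algorithm="kmeans", seed=0)
        out = order_clusters_semantic(cl, table, calcified_hu_threshold=500.0)
        assert out.semantic[0] == "calcified"
        assert out.semantic[1] == "width_rank_1"
        assert out.semantic[2] == "width_rank_2"

    def test_no_cluster_passes_threshold(self):
        table = _toy_table()
        labels = np.repeat([0, 1, 2], 20)
        cl = ClusterLabeling(labels=labels, k=3, centroids=np.zeros((3, 2)),
                             algorithm="kmeans", seed=0)
        out = order_clusters_semantic(cl, table, calcified_hu_threshold=1000.0)
        roles = set(out.semantic.values())
        assert roles == {"width_rank_1", "width_rank_2", "width_rank_3"}

    def test_invariant_to_label_permutation(self):
        table = _toy_table()
        labels = np.repeat([0, 1, 2], 20)
        perm = np.array([2, 0, 1])
        cl1 = ClusterLabeling(labels=labels, k=3, centroids=np.zeros((3, 2)),
                              algorithm="kmeans", seed=0)
        cl2 = ClusterLabeling(labels=perm[labels], k=3,
                              centroids=np.zeros((3, 2)),
                              algorithm="kmeans", seed=0)
        out1 = order_clusters_semantic(cl1, table)
        out2 = order_clusters_semantic(cl2, table)
        roles1 = [out1.semantic[l] for l in labels]
        roles2 = [out2.semantic[l] for l in perm[labels]]
        assert roles1 == roles2

    def test_exact_tie_goes_to_lower_label(self):
        table = pd.DataFrame({"mean": [600.0] * 10 + [600.0] * 10,
                              "local_radius_mm": [1.0] * 10 + [2.0] * 10})
        labels = np.repeat([0, 1], 10)
        cl = ClusterLabeling(labels=labels, k=2, centroids=np.zeros((2, 2)),
                             algorithm="kmeans", seed=0)
        out = order_clusters_semantic(cl, table, calcified_hu_threshold=500.0)
        assert out.semantic[0] == "calcified"
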
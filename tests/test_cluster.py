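import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fuzzyspike.cluster import (
    count_peaks_above_valley,
    estimate_cluster_count,
    fcm,
    fcm_memberships,
    l1_norm,
    l1_norms,
    mark_outliers,
    optimal_bin_width,
)


class TestL1Norm:
    def test_printed_example(self):
        assert l1_norm(np.array([1.0, -2.0, 3.0])) == 6.0

    def test_zero_vector(self):
        assert l1_norm(np.zeros(5)) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            l1_norm(np.array([]))

    @given(
        arrays(np.float64, 6, elements=st.floats(-100, 100)),
        arrays(np.float64, 6, elements=st.floats(-100, 100)),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_triangle_inequality(self, a, b):
        assert l1_norm(a + b) <= l1_norm(a) + l1_norm(b) + 1e-9


class TestBinWidth:
    @pytest.mark.parametrize(
        "sigma,n,expected", [(1.0, 1, 3.49), (1.0, 1000, 0.349), (2.0, 8, 3.49)]
    )
    def test_optimal_width_formula(self, sigma, n, expected):
        assert optimal_bin_width(sigma, n) == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            optimal_bin_width(0.0, 10)
        with pytest.raises(ValueError):
            optimal_bin_width(1.0, 0)


class TestClusterCount:
    def test_three_separated_gaussians(self):
        rng = np.random.default_rng(0)
        norms = np.concatenate([m + 0.5 * rng.standard_normal(300) for m in (0.0, 10.0, 20.0)])
        c, hist = estimate_cluster_count(norms)
        assert c == 3
        assert hist.W == pytest.approx(optimal_bin_width(np.std(norms, ddof=1), norms.size))

    def test_single_gaussian(self):
        rng = np.random.default_rng(1)
        c, _ = estimate_cluster_count(5.0 + rng.standard_normal(600))
        assert c == 1

    def test_minor_mode_below_valley_threshold_not_counted(self):
        # the first valley after the mode (count 55) exceeds the minor
        # bump's height (12), so the bump is treated as noise content
        counts = [100, 55, 55, 30, 8, 12, 6]
        c, mode, threshold, peaks = count_peaks_above_valley(counts)
        assert (c, mode, threshold) == (1, 0, 55.0)

    def test_trimodal_counts_give_three_peaks(self):
        counts = [5, 80, 10, 2, 60, 4, 1, 40, 3]
        c, _, threshold, peaks = count_peaks_above_valley(counts)
        assert c == 3 and list(peaks) == [1, 4, 7]

    def test_degenerate_identical_norms(self):
        c, hist = estimate_cluster_count(np.full(50, 3.0))
        assert c == 1 and hist.W == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            estimate_cluster_count(np.arange(5.0))


class TestFCM:
    def test_two_points_two_clusters_are_crisp(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0]])
        res = fcm(pts, 2)
        assert np.max(res.memberships) >= 1 - 1e-6
        assert sorted(map(tuple, np.round(res.centroids, 6).tolist())) == sorted(
            map(tuple, pts.tolist())
        )

    def test_huge_fuzziness_gives_uniform_memberships(self, blob_scores):
        """As m grows the partition tends to uniform 1/c memberships; on
        coincident centroids the value is exactly 1/c, and a converged
        m=100 run stays within a few percent of it."""
        pts, _ = blob_scores
        coincident = np.tile(pts.mean(axis=0), (3, 1)) + np.array(
            [[0.0, 0.0], [1e-12, 0.0], [0.0, 1e-12]]
        )
        u = fcm_memberships(pts, coincident, m=100.0)
        np.testing.assert_allclose(u, 1.0 / 3.0, atol=1e-9)
        res = fcm(pts, 3, m=100.0, init_centroids=coincident)
        np.testing.assert_allclose(res.memberships, 1.0 / 3.0, atol=0.05)
        assert np.max(np.abs(res.memberships - 1 / 3)) < np.max(
            np.abs(fcm(pts, 3, m=1.1).memberships - 1 / 3)
        )

    def test_blobs_match_nearest_centroid_oracle(self, blob_scores):
        pts, labels = blob_scores
        res = fcm(pts, 3, n_init=3)
        d = np.linalg.norm(pts[:, None, :] - res.centroids[None], axis=2)
        oracle = np.argmin(d, axis=1)
        assert np.array_equal(res.labels, oracle)
        # perfect agreement with ground truth up to relabeling
        mapping = {}
        for c in range(3):
            mapping[c] = np.bincount(labels[res.labels == c]).argmax()
        mapped = np.array([mapping[c] for c in res.labels])
        assert np.array_equal(mapped, labels)

    def test_near_hard_limit_reproduces_kmeans_labels(self, blob_scores):
        pts, labels = blob_scores
        res = fcm(pts, 3, m=1.01, n_init=3)
        d = np.linalg.norm(pts[:, None, :] - res.centroids[None], axis=2)
        assert np.array_equal(res.labels, np.argmin(d, axis=1))
        assert np.min(res.memberships.max(axis=1)) > 0.99

    def test_objective_non_increasing(self, blob_scores):
        pts, _ = blob_scores
        res = fcm(pts, 3)
        hist = res.objective_history
        assert np.all(np.diff(hist) <= 1e-9 * max(hist[0], 1.0))

    def test_membership_rows_sum_to_one(self, blob_scores):
        pts, _ = blob_scores
        res = fcm(pts, 3)
        np.testing.assert_allclose(res.memberships.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(res.memberships >= 0) and np.all(res.memberships <= 1)

    def test_row_permutation_permutes_labels(self, blob_scores):
        pts, _ = blob_scores
        rng = np.random.default_rng(3)
        perm = rng.permutation(pts.shape[0])
        res = fcm(pts, 3, init_centroids=pts[[0, 120, 240]])
        res_p = fcm(pts[perm], 3, init_centroids=pts[[0, 120, 240]])
        assert np.array_equal(res.labels[perm], res_p.labels)

    def test_point_on_centroid_gets_crisp_membership(self):
        centroids = np.array([[0.0, 0.0], [5.0, 0.0]])
        u = fcm_memberships(np.array([[0.0, 0.0]]), centroids, m=1.1)
        np.testing.assert_array_equal(u, [[1.0, 0.0]])

    def test_more_clusters_than_points_rejected(self):
        with pytest.raises(ValueError):
            fcm(np.zeros((2, 2)), 3)

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ValueError):
            fcm(np.array([[np.inf, 0.0], [0.0, 0.0], [1.0, 1.0]]), 2)


class TestOutliers:
    def test_far_point_flagged_center_point_not(self):
        rng = np.random.default_rng(4)
        pts = np.concatenate([rng.standard_normal((500, 2)), [[10.0, 0.0]], [[0.0, 0.0]]])
        res = fcm(pts, 1)
        flags = mark_outliers(pts, res, quantile=0.999)
        assert flags[-2]  # 10 sd along the first axis
        assert not flags[-1]  # at the centroid
        assert flags.mean() < 0.05

    def test_coincident_points_never_flagged(self):
        pts = np.zeros((30, 3))
        res = fcm(pts + 1e-12, 1)
        flags = mark_outliers(pts, res)
        assert not flags.any()
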
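"""Contours, k-means++ splitting, optimal assignment, and end-to-end tracking."""

import itertools

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from ethotrace.synthetic import MergeEvent, SceneSpec, generate_video
from ethotrace.track import (CentroidSet, ContourFilter, TrackerConfig,
                             assign_identities, extract_contours, hungarian,
                             kmeans_pp, split_merged, track)
from ethotrace.video import open_stream


class TestContours:
    def test_square_geometry(self):
        mask = np.zeros((30, 30), dtype=np.uint8)
        mask[5:15, 5:15] = 1
        (c,) = extract_contours(mask)
        assert c.area == 100
        assert c.centroid == pytest.approx((9.5, 9.5))
        assert c.length == pytest.approx(10.0, abs=0.5)

    def test_filter_drops_small_contour(self):
        mask = np.zeros((30, 30), dtype=np.uint8)
        mask[5:15, 5:15] = 1
        assert extract_contours(mask, ContourFilter(min_area=200)) == []

    def test_two_disjoint_squares(self):
        mask = np.zeros((30, 30), dtype=np.uint8)
        mask[2:8, 2:8] = 1
        mask[20:26, 20:26] = 1
        assert len(extract_contours(mask)) == 2

    def test_invalid_filter_bounds(self):
        with pytest.raises(ValueError):
            ContourFilter(min_area=10, max_area=5)


class TestSplitMerged:
    def test_separated_clusters_recovered(self, rng):
        a = rng.normal((0, 0), 0.5, (100, 2))
        b = rng.normal((50, 0), 0.5, (100, 2))
        centers, assign = split_merged(np.vstack([a, b]), 2, seed=0)
        centers = centers[np.argsort(centers[:, 0])]
        assert np.linalg.norm(centers[0] - a.mean(axis=0)) < 1
        assert np.linalg.norm(centers[1] - b.mean(axis=0)) < 1

    def test_k1_equals_mean(self, rng):
        pts = rng.uniform(0, 10, (40, 2))
        centers, _ = split_merged(pts, 1, seed=0)
        np.testing.assert_allclose(centers[0], pts.mean(axis=0), atol=1e-9)

    def test_triads_reach_brute_force_optimum(self, rng):
        def brute_phi(pts, k):
            best = np.inf
            for assign in itertools.product(range(k), repeat=len(pts)):
                if len(set(assign)) < k:
                    continue
                a = np.array(assign)
                phi = sum(((pts[a == j] - pts[a == j].mean(axis=0)) ** 2).sum()
                          for j in range(k))
                best = min(best, phi)
            return best

        for trial in range(5):
            pts = np.vstack([rng.normal(c, 0.4, (4, 2))
                             for c in [(0, 0), (10, 0), (5, 8)]])
            r = np.random.default_rng(trial)
            best = min(kmeans_pp(pts, 3, r)[2] for _ in range(20))
            assert best == pytest.approx(brute_phi(pts, 3), abs=1e-8)

    def test_objective_never_increases_and_deterministic(self, rng):
        pts = rng.uniform(0, 20, (30, 2))
        c1, a1 = split_merged(pts, 3, seed=7)
        c2, a2 = split_merged(pts, 3, seed=7)
        np.testing.assert_array_equal(c1, c2)
        np.testing.assert_array_equal(a1, a2)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            split_merged(np.zeros((2, 2)), 3, seed=0)


class TestHungarian:
    def test_matches_exhaustive_minimum_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 7))
            cost = rng.uniform(0, 10, (n, n))
            col = hungarian(cost)
            assert sorted(col.tolist()) == list(range(n))
            total = cost[np.arange(n), col].sum()
            best = min(cost[np.arange(n), list(p)].sum()
                       for p in itertools.permutations(range(n)))
            assert total == pytest.approx(best, abs=1e-9)

    def test_agrees_with_scipy(self, rng):
        cost = rng.uniform(0, 100, (8, 8))
        col = hungarian(cost)
        r, c = linear_sum_assignment(cost)
        assert cost[np.arange(8), col].sum() == pytest.approx(cost[r, c].sum())


class TestAssignIdentities:
    def test_identity_mapping_zero_cost(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        prev = CentroidSet(0, pts.copy(), np.array([1, 2, 3]))
        out = assign_identities(prev, pts.copy())
        np.testing.assert_array_equal(out.points, pts)
        np.testing.assert_array_equal(out.labels, [1, 2, 3])

    def test_single_centroid_inherits_label(self):
        prev = CentroidSet(0, np.array([[5.0, 5.0]]), np.array([4]))
        out = assign_identities(prev, np.array([[6.0, 5.0]]))
        assert out.labels.tolist() == [4]
        np.testing.assert_array_equal(out.points, [[6.0, 5.0]])

    def test_three_point_case_matches_enumeration(self):
        prev_pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        curr = np.array([[1.0, 0.0], [0.0, 9.0], [9.0, 1.0]])
        prev = CentroidSet(0, prev_pts, np.array([1, 2, 3]))
        out = assign_identities(prev, curr)
        best_perm = min(itertools.permutations(range(3)),
                        key=lambda p: sum(np.linalg.norm(prev_pts[i] - curr[p[i]])
                                          for i in range(3)))
        expected = curr[list(best_perm)]
        np.testing.assert_array_equal(out.points, expected)

    def test_missing_detection_becomes_gap(self):
        prev = CentroidSet(0, np.array([[0.0, 0.0], [50.0, 50.0]]), np.array([1, 2]))
        out = assign_identities(prev, np.array([[1.0, 0.0]]))
        assert not np.isnan(out.points[0]).any()
        assert np.isnan(out.points[1]).all()

    def test_empty_raises(self):
        prev = CentroidSet(0, np.array([[0.0, 0.0]]), np.array([1]))
        with pytest.raises(ValueError):
            assign_identities(prev, np.zeros((0, 2)))


def _match_permutation(xy, gt):
    """Best fixed permutation aligning tracker identities with ground truth."""
    n = xy.shape[1]
    best = None
    for perm in itertools.permutations(range(n)):
        err = np.nanmax(np.linalg.norm(xy[:, perm, :] - gt, axis=2))
        if best is None or err < best[0]:
            best = (err, perm)
    return best


class TestTrackPipeline:
    def test_non_crossing_blobs_tracked_within_one_pixel(self, lane_video):
        path, truth, spec = lane_video
        cfg = TrackerConfig(n_individuals=3, contour_filter=ContourFilter(min_area=30))
        ts = track(open_stream(path), cfg)
        assert ts.xy.shape == (spec.duration, 3, 2)
        assert not np.isnan(ts.xy).any()
        err, _ = _match_permutation(ts.xy, truth.positions())
        assert err < 1.0

    def test_identities_never_switch_on_non_crossing_video(self, lane_video):
        path, truth, _ = lane_video
        cfg = TrackerConfig(n_individuals=3, contour_filter=ContourFilter(min_area=30))
        ts = track(open_stream(path), cfg)
        gt = truth.positions()
        # per-frame nearest ground-truth blob of each tracked identity
        owner = np.array([
            [int(np.argmin(np.linalg.norm(gt[f] - ts.xy[f, j], axis=1)))
             for j in range(3)] for f in range(ts.n_frames)])
        assert (owner == owner[0]).all(), "identity switch detected"

    def test_stationary_blob_constant_trajectory(self, single_blob_video):
        path, truth, spec = single_blob_video
        cfg = TrackerConfig(n_individuals=1, contour_filter=ContourFilter(min_area=30))
        ts = track(open_stream(path), cfg)
        assert np.nanmax(np.ptp(ts.xy[:, 0, 0])) < 0.5
        assert np.nanmax(np.ptp(ts.xy[:, 0, 1])) < 0.5

    def test_merge_split_keeps_group_size_and_identities(self, tmp_path):
        spec = SceneSpec(n_blobs=2, speed=2.0, duration=80, seed=11,
                         merge_events=(MergeEvent(a=0, b=1, start=35, duration=5),))
        path = tmp_path / "merge.avi"
        truth = generate_video(spec, path)
        cfg = TrackerConfig(n_individuals=2, contour_filter=ContourFilter(min_area=30), seed=1)
        ts = track(open_stream(path), cfg)
        # exactly 2 centroids in every frame, including the merged ones
        assert not np.isnan(ts.xy).any()
        gt = truth.positions()
        # identities consistent before and after the merge window
        pre = np.array([int(np.argmin(np.linalg.norm(gt[10] - ts.xy[10, j], axis=1)))
                        for j in range(2)])
        post = np.array([int(np.argmin(np.linalg.norm(gt[70] - ts.xy[70, j], axis=1)))
                         for j in range(2)])
        np.testing.assert_array_equal(pre, post)
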
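"""Kinematic statistics: closed forms, oracle re-evaluation, invariants."""

import numpy as np
import pytest

from ethotrace.kinematics import (KinematicConfig, activity_times,
                                  compute_report, detection_rate,
                                  group_state_series, group_times,
                                  interactions, meandering, network_density,
                                  time_in_region, tracked_distance,
                                  turning_angle, velocities)
from ethotrace.trajectory import TrajectorySet
from ethotrace.video import Roi


def _ts(xy, fps=30.0, scale=1.0):
    return TrajectorySet(xy=np.asarray(xy, dtype=float), fps=fps, scale=scale)


class TestTrackedDistance:
    def test_stationary_is_zero(self):
        traj = np.tile([3.0, 4.0], (10, 1))
        assert tracked_distance(traj) == 0.0

    def test_345_triangle(self):
        assert tracked_distance(np.array([[0.0, 0.0], [3.0, 4.0]])) == 5.0

    def test_random_walk_matches_resummation(self, rng):
        traj = np.cumsum(rng.normal(0, 1, (101, 2)), axis=0)
        expected = sum(float(np.hypot(*(traj[i + 1] - traj[i]))) for i in range(100))
        assert tracked_distance(traj) == pytest.approx(expected, rel=1e-12)

    def test_gap_contributes_no_step(self):
        traj = np.array([[0.0, 0.0], [np.nan, np.nan], [10.0, 0.0]])
        assert tracked_distance(traj) == 0.0


class TestVelocities:
    def test_constant_speed(self):
        traj = np.column_stack([np.arange(30) * 2.0, np.zeros(30)])
        mean, vmax = velocities(traj, fps=30)
        assert vmax == pytest.approx(60.0)
        # mean = td / duration = 58 steps... (29 steps * 2 px) / 1 s
        assert mean == pytest.approx(58.0)

    def test_stationary_zero(self):
        traj = np.tile([1.0, 1.0], (10, 1))
        mean, vmax = velocities(traj, fps=10)
        assert (mean, vmax) == (0.0, 0.0)

    def test_max_picks_jump(self):
        xs = np.concatenate([np.arange(10.0), [19.0], np.arange(20.0, 25.0)])
        traj = np.column_stack([xs, np.zeros_like(xs)])
        _, vmax = velocities(traj, fps=5)
        assert vmax == pytest.approx(10 * 5)

    def test_zero_duration_errors(self):
        with pytest.raises(ValueError):
            velocities(np.zeros((2, 2)), fps=0)


class TestAngles:
    def test_straight_line_zero(self):
        traj = np.column_stack([np.arange(10.0), np.zeros(10)])
        assert turning_angle(traj) == 0.0
        assert meandering(traj) == 0.0

    def test_diagonal_unit_steps(self):
        n = 8
        traj = np.column_stack([np.arange(n + 1.0), np.arange(n + 1.0)])
        assert turning_angle(traj) == pytest.approx(45.0)
        assert meandering(traj) == pytest.approx(45.0 / np.sqrt(2))

    def test_vertical_step_is_90(self):
        traj = np.array([[0.0, 0.0], [0.0, 5.0]])
        assert turning_angle(traj) == pytest.approx(90.0)

    def test_random_trajectory_matches_stepwise_oracle(self, rng):
        traj = np.cumsum(rng.normal(0, 2, (50, 2)), axis=0)
        angles = []
        for i in range(49):
            dx, dy = traj[i + 1] - traj[i]
            angles.append(abs(np.degrees(np.arctan(dy / dx))) if dx != 0 else 90.0)
        assert turning_angle(traj) == pytest.approx(np.mean(angles), rel=1e-9)
        td = tracked_distance(traj)
        assert meandering(traj) == pytest.approx(np.sum(angles) / td, rel=1e-9)


class TestActivityTimes:
    def test_all_resting(self):
        traj = np.tile([0.0, 0.0], (31, 1))
        rest, mid, fast = activity_times(traj, tl=0.046, th=1.0, fps=30)
        assert rest == pytest.approx(30 / 30)
        assert mid == fast == 0.0

    def test_all_fast(self):
        traj = np.column_stack([np.arange(0, 50.0, 5), np.zeros(10)])
        rest, mid, fast = activity_times(traj, tl=0.1, th=1.0, fps=9)
        assert fast == pytest.approx(1.0)

    def test_boundary_step_counts_as_resting(self):
        traj = np.array([[0.0, 0.0], [0.046, 0.0]])
        rest, mid, fast = activity_times(traj, tl=0.046, th=1.0, fps=1)
        assert rest == 1.0 and mid == 0.0


class TestInteractions:
    def test_far_apart_zero_centrality(self):
        xy = np.stack([np.tile([0.0, 0.0], (5, 1)), np.tile([100.0, 0.0], (5, 1))], axis=1)
        _, centrality = interactions(_ts(xy), ti=10)
        assert centrality.tolist() == [0, 0]

    def test_coincident_ten_frames(self):
        xy = np.zeros((10, 2, 2))
        _, centrality = interactions(_ts(xy), ti=1)
        assert centrality.tolist() == [10, 10]

    def test_triangle_one_frame(self):
        xy = np.array([[[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]])
        pairs, centrality = interactions(_ts(xy), ti=2)
        assert len(pairs[0]) == 3
        assert centrality.tolist() == [2, 2, 2]


class TestNetworkDensity:
    def test_complete_graph(self):
        xy = np.zeros((3, 5, 2))
        assert network_density(_ts(xy), ti=1) == 1.0

    def test_no_interactions(self):
        xy = np.stack([np.tile([100.0 * j, 0.0], (3, 1)) for j in range(5)], axis=1)
        assert network_density(_ts(xy), ti=1) == 0.0

    def test_star_of_four_edges(self):
        # hub at origin; 4 spokes within ti of the hub but not of each other
        spokes = np.array([[5.0, 0], [-5.0, 0], [0, 5.0], [0, -5.0]])
        xy = np.concatenate([[[0.0, 0.0]], spokes])[None, :, :]
        assert network_density(_ts(xy), ti=6) == pytest.approx(0.4)

    def test_single_individual_errors(self):
        with pytest.raises(ValueError):
            network_density(_ts(np.zeros((3, 1, 2))), ti=1)


class TestTimeInRegion:
    def test_fully_inside(self):
        roi = Roi("circle", center=(0, 0), radius=10)
        traj = np.tile([1.0, 1.0], (30, 1))
        assert time_in_region(traj, roi, fps=30) == pytest.approx(1.0)

    def test_fully_outside(self):
        roi = Roi("circle", center=(0, 0), radius=1)
        traj = np.tile([50.0, 50.0], (30, 1))
        assert time_in_region(traj, roi, fps=30) == 0.0

    def test_half_inside(self):
        roi = Roi("circle", center=(0, 0), radius=5)
        traj = np.vstack([np.tile([0.0, 0.0], (15, 1)), np.tile([50.0, 0.0], (15, 1))])
        assert time_in_region(traj, roi, fps=30) == pytest.approx(0.5)


class TestGroupStates:
    def test_all_moving_east_polarized(self):
        t = np.arange(10.0)
        xy = np.stack([np.column_stack([t, np.zeros(10)]),
                       np.column_stack([t, np.full(10, 5.0)])], axis=1)
        states = group_state_series(_ts(xy))
        assert all(s.p == pytest.approx(1.0) for s in states)

    def test_opposite_directions_cancel(self):
        t = np.arange(10.0)
        xy = np.stack([np.column_stack([t, np.zeros(10)]),
                       np.column_stack([-t, np.full(10, 5.0)])], axis=1)
        states = group_state_series(_ts(xy))
        assert all(s.p == pytest.approx(0.0, abs=1e-12) for s in states)

    def test_perfect_vortex(self):
        # 4 individuals rotating on a circle: tangential motion, radial d
        frames = 20
        theta0 = np.array([0, np.pi / 2, np.pi, 3 * np.pi / 2])
        xy = np.zeros((frames, 4, 2))
        for f in range(frames):
            ang = theta0 + 0.01 * f
            xy[f, :, 0] = 10 * np.cos(ang)
            xy[f, :, 1] = 10 * np.sin(ang)
        states = group_state_series(_ts(xy))
        for s in states:
            assert s.r == pytest.approx(1.0, abs=1e-3)
            assert s.p == pytest.approx(0.0, abs=1e-9)

    def test_stationary_frame_is_undefined(self):
        xy = np.zeros((3, 2, 2))
        states = group_state_series(_ts(xy))
        assert all(np.isnan(s.p) and np.isnan(s.r) for s in states)


class TestGroupTimes:
    def _mk(self, p, r, n=30):
        from ethotrace.kinematics import GroupFrameState

        return [GroupFrameState(i, p, r) for i in range(n)]

    def test_polarized_throughout(self):
        gp, gs, gm = group_times(self._mk(1.0, 0.0), fps=30)
        assert (gp, gs, gm) == (1.0, 0.0, 0.0)

    def test_midband_counts_nothing(self):
        assert group_times(self._mk(0.5, 0.5), fps=30) == (0.0, 0.0, 0.0)

    def test_milling(self):
        gp, gs, gm = group_times(self._mk(0.1, 0.9), fps=30)
        assert gm == 1.0 and gp == 0.0 and gs == 0.0


class TestDetectionRate:
    def test_uniform_speed_no_gaps(self):
        t = np.arange(100.0)
        xy = np.stack([np.column_stack([t, np.zeros(100)])], axis=1)
        assert detection_rate(_ts(xy)) == 1.0

    def test_one_teleport_among_hundred_steps(self):
        xs = np.arange(101.0)
        xs[51:] += 50.0  # one 51-px step among 100 unit steps
        xy = np.column_stack([xs, np.zeros(101)])[:, None, :]
        assert detection_rate(_ts(xy)) == pytest.approx(0.99)

    def test_gap_fraction_reduces_rate(self):
        t = np.arange(100.0)
        xy = np.column_stack([t, np.zeros(100)])[:, None, :].copy()
        xy[90:, 0, :] = np.nan  # 10% undetected
        assert detection_rate(_ts(xy)) == pytest.approx(0.9)

    def test_single_frame_errors(self):
        with pytest.raises(ValueError):
            detection_rate(_ts(np.zeros((1, 1, 2))))


class TestReportInvariants:
    def test_scale_covariance(self, rng):
        xy = np.cumsum(rng.normal(0, 2, (40, 3, 2)), axis=0) + 100
        cfg = KinematicConfig(tl=0.1, th=5.0, ti=10.0)
        r1 = compute_report(_ts(xy, scale=1.0), cfg)
        r2 = compute_report(_ts(xy, scale=2.0), cfg)
        np.testing.assert_allclose(r2.individuals["tracked_distance"],
                                   2 * r1.individuals["tracked_distance"])
        np.testing.assert_allclose(r2.individuals["mean_velocity"],
                                   2 * r1.individuals["mean_velocity"])
        np.testing.assert_allclose(r2.individuals["turning_angle_deg"],
                                   r1.individuals["turning_angle_deg"])
        assert r2.network_density == r1.network_density

    def test_times_bounded_by_duration(self, rng):
        xy = np.cumsum(rng.normal(0, 1, (60, 2, 2)), axis=0)
        ts = _ts(xy, fps=30)
        cfg = KinematicConfig(tl=0.5, th=2.0, ti=5.0)
        rep = compute_report(ts, cfg)
        for _, row in rep.individuals.iterrows():
            total = row["resting_time_s"] + row["mean_movement_time_s"] + row["fast_movement_time_s"]
            assert total <= ts.duration + 1e-9
        assert 0 <= rep.detection_rate <= 1
        assert 0 <= rep.network_density <= 1
        assert rep.group_polarized_time + rep.group_swarming_time + rep.group_milling_time <= ts.duration
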
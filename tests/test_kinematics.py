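import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.spatial.transform import Rotation

from lymphwalk import kinematics
from lymphwalk.kinematics import (normalize_by_track_mean, segment_steps,
                                  speeds, turning_angle_values, velocities)

from conftest import make_track, straight_track


def brute_force_steps(track, theta_max, mode="first"):
    """Independent scalar reimplementation of the greedy segmentation."""
    disp = [track.xyz[i + 1] - track.xyz[i] for i in range(track.n_positions - 1)]
    boundaries = [0]
    ref = None
    for i, d in enumerate(disp):
        norm = math.sqrt(sum(c * c for c in d))
        if norm == 0:
            continue
        u = d / norm
        if ref is None:
            ref = u
            continue
        cosang = max(-1.0, min(1.0, float(sum(a * b for a, b in zip(ref, u)))))
        if math.degrees(math.acos(cosang)) > theta_max:
            boundaries.append(i)
            ref = u
        elif mode == "previous":
            ref = u
    boundaries.append(len(disp))
    return [(boundaries[j], boundaries[j + 1]) for j in range(len(boundaries) - 1)]


class TestVelocities:
    def test_straight_constant_speed(self):
        v = velocities(straight_track(n=6, speed=0.2))
        assert np.allclose(v, v[0])
        assert np.linalg.norm(v[0]) == pytest.approx(0.2)

    def test_two_point_norm(self):
        tr = make_track([[0, 0, 0], [6, 0, 0]], dt=60.0)
        v = velocities(tr)
        assert v.shape == (1, 3)
        assert np.linalg.norm(v[0]) == pytest.approx(0.1)

    def test_stationary_zero_vectors(self):
        assert np.all(velocities(make_track(np.zeros((4, 3)))) == 0)

    def test_duplicate_timestamps_error(self):
        tr = make_track(np.zeros((3, 3)))
        tr.t = np.array([0.0, 15.0, 15.0])
        with pytest.raises(ValueError, match="duplicate"):
            velocities(tr)

    def test_speeds_unit_conversion(self):
        tr = straight_track(n=4, speed=0.1)
        assert np.allclose(speeds(tr, per_minute=True), 6.0)


class TestTurningAngles:
    @pytest.mark.parametrize("third,expected", [
        ([2, 0, 0], 0.0), ([0, 0, 0], 180.0), ([1, 1, 0], 90.0)])
    def test_canonical_angles(self, third, expected):
        tr = make_track([[0, 0, 0], [1, 0, 0], third])
        angles = turning_angle_values(tr)
        assert angles[0] == pytest.approx(expected, abs=1e-9)

    def test_rigid_motion_invariance(self, rng):
        xyz = np.cumsum(rng.normal(0, 2, (10, 3)), axis=0)
        base = turning_angle_values(make_track(xyz))
        R = Rotation.random(random_state=3).as_matrix()
        moved = turning_angle_values(make_track(xyz @ R.T + [50, -20, 7]))
        np.testing.assert_allclose(base, moved, atol=1e-8)

    def test_zero_vectors_skipped(self):
        xyz = [[0, 0, 0], [1, 0, 0], [1, 0, 0], [2, 0, 0]]
        angles = turning_angle_values(make_track(xyz))
        # the stationary frame contributes no angle; remaining pair is collinear
        assert list(angles) == [pytest.approx(0.0)]


class TestSegmentSteps:
    def test_straight_track_is_one_step(self):
        tr = straight_track(n=5, speed=0.2)
        steps = segment_steps(tr)
        assert len(steps) == 1
        assert steps[0].length == pytest.approx(tr.path_length)
        assert steps[0].duration == pytest.approx(tr.duration)

    def test_single_right_angle_turn_gives_two_steps(self):
        xyz = [[0, 0, 0], [1, 0, 0], [2, 0, 0], [2, 1, 0], [2, 2, 0]]
        assert len(segment_steps(make_track(xyz))) == 2

    def test_threshold_180_gives_one_step(self, rng):
        xyz = np.cumsum(rng.normal(0, 2, (15, 3)), axis=0)
        assert len(segment_steps(make_track(xyz), theta_max=180.0)) == 1

    @pytest.mark.parametrize("theta", [0.0, -5.0, 181.0])
    def test_invalid_threshold(self, theta):
        with pytest.raises(ValueError):
            segment_steps(straight_track(), theta_max=theta)

    def test_partition_invariants(self, rng):
        for _ in range(10):
            tr = make_track(np.cumsum(rng.normal(0, 2, (12, 3)), axis=0))
            steps = segment_steps(tr)
            assert sum(s.duration for s in steps) == pytest.approx(tr.duration)
            np.testing.assert_allclose(
                np.sum([s.vector for s in steps], axis=0),
                tr.xyz[-1] - tr.xyz[0], atol=1e-9)

    def test_step_count_non_increasing_in_threshold(self, rng):
        thresholds = [5, 15, 30, 60, 120, 180]
        for _ in range(5):
            tr = make_track(np.cumsum(rng.normal(0, 2, (20, 3)), axis=0))
            counts = [len(segment_steps(tr, th)) for th in thresholds]
            assert counts == sorted(counts, reverse=True)

    @pytest.mark.parametrize("mode", ["first", "previous"])
    def test_matches_brute_force_oracle(self, mode, rng):
        for _ in range(20):
            n = int(rng.integers(3, 20))
            tr = make_track(np.cumsum(rng.normal(0, 2, (n, 3)), axis=0))
            theta = float(rng.uniform(5, 90))
            got = [(s.start_index, s.end_index)
                   for s in segment_steps(tr, theta, mode=mode)]
            assert got == brute_force_steps(tr, theta, mode)

    def test_zero_displacements_absorbed(self):
        xyz = [[0, 0, 0], [1, 0, 0], [1, 0, 0], [2, 0, 0]]
        steps = segment_steps(make_track(xyz))
        assert len(steps) == 1
        assert steps[0].length == pytest.approx(2.0)


positions = arrays(np.float64, st.tuples(st.integers(2, 12), st.just(3)),
                   elements=st.floats(-50, 50, allow_nan=False,
                                      allow_infinity=False))


class TestSegmentStepProperties:
    @given(xyz=positions, theta=st.floats(1.0, 180.0))
    @settings(max_examples=60, deadline=None)
    def test_steps_partition_track(self, xyz, theta):
        tr = make_track(xyz)
        steps = segment_steps(tr, theta)
        assert steps[0].start_index == 0
        assert steps[-1].end_index == tr.n_positions - 1
        for a, b in zip(steps[:-1], steps[1:]):
            assert a.end_index == b.start_index
        assert sum(s.duration for s in steps) == pytest.approx(tr.duration)

    @given(xyz=positions)
    @settings(max_examples=60, deadline=None)
    def test_turning_angles_within_range(self, xyz):
        tr = make_track(xyz)
        if tr.n_positions < 3:
            return
        angles = kinematics.turning_angle_values(tr)
        assert np.all((angles >= 0.0) & (angles <= 180.0))


class TestNormalize:
    def test_each_track_unit_mean(self, rng):
        vals = [rng.gamma(2, 3, 20), rng.gamma(5, 1, 15)]
        out = normalize_by_track_mean(vals)
        for v in out:
            assert np.mean(v) == pytest.approx(1.0)

    def test_constant_track_all_ones(self):
        (out,) = normalize_by_track_mean([np.full(5, 3.3)])
        assert np.allclose(out, 1.0)

    def test_zero_mean_excluded(self):
        out = normalize_by_track_mean([np.zeros(5), np.ones(5)])
        assert len(out) == 1
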
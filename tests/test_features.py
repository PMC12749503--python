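import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kinescore.features import (DegenerateGeometryError, JointAngleSeries,
                                JointDefinition, angle_series,
                                angular_velocity, joint_angle, load_joints,
                                range_of_motion, standardize,
                                summarize_repetitions)
from kinescore.preprocessing import to_pixel
from kinescore.repetition import filter_stable, segment_repetitions
from kinescore.synthetic import (DrivenJoint, SyntheticMotionSpec,
                                 forward_kinematics, generate_angle_trajectory,
                                 simulate)


def atan2_angle(p, v, d):
    """Independent oracle: angle via atan2(|cross|, dot)."""
    a = np.subtract(p, v)
    b = np.subtract(d, v)
    return math.degrees(math.atan2(abs(a[0] * b[1] - a[1] * b[0]), a @ b))


class TestJointAngle:
    @pytest.mark.parametrize("p,v,d,expected", [
        ((0, 0), (0, 1), (1, 1), 90.0),
        ((0, 0), (1, 0), (2, 0), 180.0),
        ((1, 1), (0, 0), (2, 2), 0.0),
    ])
    def test_canonical_geometries(self, p, v, d, expected):
        # arccos conditioning near 0/180 deg limits accuracy to ~sqrt(eps)
        assert joint_angle(p, v, d) == pytest.approx(expected, abs=2e-6)

    def test_matches_atan2_oracle(self):
        assert joint_angle((2, 1), (4, 5), (7, 3)) == pytest.approx(
            atan2_angle((2, 1), (4, 5), (7, 3)), abs=1e-9)

    @given(st.lists(st.floats(-100, 100), min_size=6, max_size=6))
    @settings(max_examples=200, deadline=None)
    def test_arccos_equals_atan2_oracle(self, flat):
        p, v, d = (flat[0], flat[1]), (flat[2], flat[3]), (flat[4], flat[5])
        a = np.subtract(p, v)
        b = np.subtract(d, v)
        if np.hypot(*a) < 1e-6 or np.hypot(*b) < 1e-6:
            return
        # 1e-9 agreement away from collinearity; arccos conditioning
        # degrades to ~sqrt(eps) as the angle approaches 0 or 180
        oracle = atan2_angle(p, v, d)
        tol = 1e-9 if 1.0 < oracle < 179.0 else 5e-6
        assert joint_angle(p, v, d) == pytest.approx(oracle, abs=tol)

    @given(tx=st.floats(-50, 50), ty=st.floats(-50, 50),
           rot=st.floats(0, 2 * math.pi), scale=st.floats(0.01, 100))
    @settings(max_examples=200, deadline=None)
    def test_similarity_transform_invariance(self, tx, ty, rot, scale):
        pts = np.array([[2.0, 1.0], [4.0, 5.0], [7.0, 3.0]])
        c, s = math.cos(rot), math.sin(rot)
        R = np.array([[c, -s], [s, c]])
        moved = scale * pts @ R.T + [tx, ty]
        assert joint_angle(*moved) == pytest.approx(joint_angle(*pts), abs=1e-9)

    def test_zero_length_vector_raises(self):
        with pytest.raises(DegenerateGeometryError):
            joint_angle((1, 1), (1, 1), (2, 2))

    def test_signed_mode_admits_reflex_angles(self):
        # distal rotated 250 degrees counterclockwise from proximal
        r = math.radians(250)
        assert joint_angle((1, 0), (0, 0), (math.cos(r), math.sin(r)),
                           signed=True) == pytest.approx(250.0, abs=1e-9)
        assert joint_angle((1, 0), (0, 0), (math.cos(r), math.sin(r))) == \
            pytest.approx(110.0, abs=1e-9)


class TestAngleSeries:
    def test_static_pose_constant_series(self, static_sequence):
        joint = load_joints()["right_elbow"]
        series = angle_series(to_pixel(static_sequence), joint)
        assert series.valid.all()
        assert np.ptp(series.angles) == pytest.approx(0.0, abs=1e-9)

    def test_elbow_sweep_recovers_driving_angles(self):
        driven = np.linspace(45, 135, 60)
        seq = forward_kinematics({"right_elbow": driven}, fps=30)
        series = angle_series(to_pixel(seq), load_joints()["right_elbow"])
        np.testing.assert_allclose(series.angles, driven, atol=1e-6)

    def test_dropped_wrist_invalidates_only_that_frame(self, make_sequence,
                                                       knee_sequence):
        knee_sequence.frames[4].landmarks[16].visibility = 0.0  # right wrist
        pix = to_pixel(knee_sequence)
        pix.valid = pix.visibility >= 0.5
        series = angle_series(pix, load_joints()["right_elbow"])
        assert not series.valid[4]
        assert series.valid[3] and series.valid[5]
        # the knee does not use the wrist
        knee = angle_series(pix, load_joints()["right_knee"])
        assert knee.valid.all()


class TestRangeOfMotion:
    def _series(self, angles, valid=None):
        angles = np.asarray(angles, dtype=float)
        if valid is None:
            valid = np.isfinite(angles)
        return JointAngleSeries(joint=JointDefinition("j", (0, 1, 2)),
                                angles=angles, valid=valid, fps=30)

    def test_hip_sagittal_worked_example(self):
        summ = range_of_motion(self._series([45.0, 120.0, 180.0, 60.0]))
        assert summ.rom == 135.0
        assert (summ.theta_max, summ.theta_min) == (180.0, 45.0)

    def test_constant_series_zero_rom(self):
        assert range_of_motion(self._series([90.0] * 5)).rom == 0.0

    def test_raised_cosine_rom_is_twice_amplitude(self):
        theta = generate_angle_trajectory(90, 60, 3, fps=60, duration=6)
        summ = range_of_motion(self._series(theta))
        assert summ.rom == pytest.approx(60.0, abs=1e-6)

    def test_no_valid_frame_raises(self):
        with pytest.raises(ValueError):
            range_of_motion(self._series([np.nan, np.nan]))


class TestAngularVelocity:
    def _series(self, angles, fps=30.0):
        angles = np.asarray(angles, dtype=float)
        return JointAngleSeries(joint=JointDefinition("j", (0, 1, 2)),
                                angles=angles,
                                valid=np.ones(angles.size, bool), fps=fps)

    def test_constant_series_zero(self):
        v = angular_velocity(self._series([90.0] * 10)).values
        np.testing.assert_allclose(v, 0.0)

    def test_linear_ramp_exact(self):
        k, fps = 2.0, 60.0
        theta = 30 + k * np.arange(20)
        v = angular_velocity(self._series(theta, fps)).values
        np.testing.assert_allclose(v, k * fps, rtol=1e-12)

    @pytest.mark.parametrize("fps", [30.0, 60.0])
    def test_sinusoid_within_taylor_bound(self, fps):
        A, omega, c = 30.0, 2 * math.pi * 0.5, 90.0
        t = np.arange(int(4 * fps)) / fps
        theta = A * np.sin(omega * t) + c
        v = angular_velocity(self._series(theta, fps)).values
        exact = A * omega * np.cos(omega * t)
        bound = A * omega ** 3 / (6 * fps ** 2)  # |theta'''| h^2 / 6
        assert np.abs(v[1:-1] - exact[1:-1]).max() <= bound * 1.001

    def test_second_order_convergence(self):
        A, omega = 30.0, 2 * math.pi * 0.5
        errs = []
        for fps in (30.0, 60.0):
            t = np.arange(int(4 * fps)) / fps
            theta = A * np.sin(omega * t)
            v = angular_velocity(self._series(theta, fps)).values
            errs.append(np.abs(v[1:-1] - A * omega * np.cos(omega * t[1:-1])).max())
        assert errs[1] < errs[0] / 3.5  # ~4x at doubled rate

    def test_too_few_frames_raises(self):
        with pytest.raises(ValueError):
            angular_velocity(self._series([1.0, 2.0]))


class TestStandardize:
    def test_hand_computed_population_sd(self):
        out = standardize([1.0, 2.0, 3.0])
        np.testing.assert_allclose(out.values, [-1.224744871, 0, 1.224744871],
                                   atol=1e-9)
        assert out.sigma == pytest.approx(math.sqrt(2 / 3))

    @given(a=st.floats(0.01, 100), b=st.floats(-100, 100))
    @settings(max_examples=100, deadline=None)
    def test_affine_invariance(self, a, b):
        x = np.array([0.3, -1.2, 4.5, 2.2, -0.7])
        np.testing.assert_allclose(standardize(a * x + b).values,
                                   standardize(x).values, atol=1e-6)

    def test_idempotence(self):
        x = np.random.default_rng(1).normal(size=50)
        once = standardize(x).values
        np.testing.assert_allclose(standardize(once).values, once, atol=1e-9)

    def test_constant_series_flagged(self):
        out = standardize([5.0] * 8)
        assert out.constant
        np.testing.assert_array_equal(out.values, 0.0)


class TestSummarizeRepetitions:
    def _measured(self, spec):
        seq = simulate(spec)
        series = angle_series(to_pixel(seq), load_joints()["right_knee"])
        reps = filter_stable(segment_repetitions(series), series)
        return series, reps

    def test_identical_repetitions_zero_sd(self, knee_spec):
        series, reps = self._measured(knee_spec)
        summ = summarize_repetitions(series, reps)
        assert summ.n_repetitions == 5
        assert summ.rom_sd == pytest.approx(0.0, abs=0.2)
        assert summ.rom == pytest.approx(110.0, abs=1.0)

    def test_single_repetition_convention(self):
        spec = SyntheticMotionSpec(
            driven=[DrivenJoint("right_knee", 60, 100, 1)], fps=30, duration=3)
        series, reps = self._measured(spec)
        summ = summarize_repetitions(series, reps)
        assert summ.single_repetition
        assert summ.rom_sd == 0.0 and summ.velocity_sd == 0.0

    def test_varied_rep_rom_recovered(self):
        """Five reps whose ROM varies rep-to-rep around 100 deg: the
        across-rep mean tracks the generated mean within 1 deg and the sd
        within 2 deg."""
        rng = np.random.default_rng(42)
        roms = 100 + rng.normal(0, 5, size=5)
        fps, per_rep = 30.0, 3.0
        pieces = [generate_angle_trajectory(60, r, 1, fps, per_rep) for r in roms]
        theta = np.concatenate(pieces)
        seq = forward_kinematics({"right_knee": theta}, fps=fps)
        series = angle_series(to_pixel(seq), load_joints()["right_knee"])
        reps = filter_stable(segment_repetitions(series), series)
        summ = summarize_repetitions(series, reps)
        assert summ.n_repetitions == 5
        assert summ.rom == pytest.approx(roms.mean(), abs=1.0)
        assert summ.rom_sd == pytest.approx(roms.std(ddof=1), abs=2.0)

    def test_no_accepted_reps_raises(self):
        series = JointAngleSeries(joint=JointDefinition("j", (0, 1, 2)),
                                  angles=np.zeros(10),
                                  valid=np.ones(10, bool), fps=30)
        from kinescore.repetition import RepetitionSet
        with pytest.raises(ValueError):
            summarize_repetitions(series, RepetitionSet(segments=[]))
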
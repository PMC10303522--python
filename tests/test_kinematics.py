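"""Quaternion algebra, mounting calibration and joint-angle recovery."""

import numpy as np
import pytest

from emgkin.kinematics import (PoseStream, SegmentModel, body_orientation,
                               calibrate_mounting, joint_angles, q_conjugate,
                               q_from_axis_angle, q_multiply, q_normalize,
                               q_rotate, vector_angle)
from emgkin.synthetic import (GaitProfile, gen_angles, gen_pose_streams,
                              random_mounting)

IDENT = np.array([1.0, 0.0, 0.0, 0.0])
Z90 = q_from_axis_angle(np.array([0.0, 0.0, 1.0]), np.pi / 2)


class TestQuaternionOps:
    def test_identity_rotation(self):
        v = np.array([0.3, -1.2, 2.0])
        assert np.allclose(q_rotate(IDENT, v), v)

    def test_canonical_z_rotation(self):
        assert np.allclose(q_rotate(Z90, np.array([1.0, 0.0, 0.0])),
                           [0.0, 1.0, 0.0], atol=1e-9)

    def test_conjugate_round_trip(self):
        q = q_normalize(np.array([0.3, 0.5, -0.7, 0.2]))
        v = np.array([1.0, 2.0, 3.0])
        assert np.allclose(q_rotate(q, q_rotate(q_conjugate(q), v)), v, atol=1e-12)

    def test_hamilton_product_composes_rotations(self):
        # rotating by q1 then q2 equals rotating by q2 ⊗ q1
        q1 = q_from_axis_angle(np.array([1.0, 0, 0]), 0.4)
        q2 = q_from_axis_angle(np.array([0.0, 1, 0]), -0.9)
        v = np.array([0.2, -0.5, 1.1])
        assert np.allclose(q_rotate(q2, q_rotate(q1, v)),
                           q_rotate(q_multiply(q2, q1), v), atol=1e-12)

    def test_non_unit_rejected(self):
        with pytest.raises(ValueError):
            q_rotate(np.array([2.0, 0, 0, 0]), np.zeros(3))

    def test_scipy_rotation_cross_check(self):
        # independent oracle: scipy uses scalar-last quaternions
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(7)
        q = q_normalize(rng.standard_normal(4))
        v = rng.standard_normal(3)
        ref = Rotation.from_quat(np.r_[q[1:], q[0]]).apply(v)
        assert np.allclose(q_rotate(q, v), ref, atol=1e-12)


class TestCalibration:
    def test_identity(self):
        assert np.allclose(calibrate_mounting(IDENT), IDENT)

    def test_x45_gives_conjugate(self):
        q = q_from_axis_angle(np.array([1.0, 0, 0]), np.pi / 4)
        assert np.allclose(calibrate_mounting(q), q_conjugate(q))

    def test_random_mounting_recovered(self):
        rng = np.random.default_rng(3)
        m = random_mounting(rng)
        block = np.tile(m, (50, 1))
        rec = calibrate_mounting(block)
        # recovered mounting equals the conjugate to numerical precision
        d = q_multiply(rec, m)
        assert abs(abs(d[0]) - 1.0) < 1e-9

    def test_non_static_warns(self):
        angs = np.linspace(0, np.radians(10), 20)
        q = q_from_axis_angle(np.array([0.0, 1, 0]), angs)
        with pytest.warns(UserWarning):
            calibrate_mounting(q)

    def test_body_orientation_identity_at_init(self):
        rng = np.random.default_rng(5)
        m = random_mounting(rng)
        qb = body_orientation(m, calibrate_mounting(m))
        assert abs(abs(qb[0]) - 1.0) < 1e-9
        assert np.allclose(body_orientation(m, IDENT), m)


class TestVectorAngle:
    @pytest.mark.parametrize("u,w,expected", [
        ((1, 0, 0), (1, 0, 0), 0.0),
        ((1, 0, 0), (0, 1, 0), 90.0),
        ((1, 0, 0), (-1, 0, 0), 180.0),
    ])
    def test_examples(self, u, w, expected):
        assert vector_angle(np.array(u, float), np.array(w, float)) == pytest.approx(expected)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            vector_angle(np.zeros(3), np.ones(3))


class TestJointAngles:
    def _streams(self, hip_deg, knee_deg, fs=100.0, calib_s=1.0, seed=0,
                 mountings=None):
        angles = gen_angles(GaitProfile(
            n_cycles=1, fs=fs, cycle_duration_s=hip_deg.size / fs,
            amplitude_variability=0.0), seed=seed)
        angles.hip_deg = hip_deg
        angles.knee_deg = knee_deg
        poses, m, calib = gen_pose_streams(angles, mountings=mountings,
                                           seed=seed, calib_duration_s=calib_s)
        return poses, calib

    def test_neutral_standing(self):
        n = 200
        poses, calib = self._streams(np.zeros(n), np.zeros(n))
        ja = joint_angles(poses["waist"], poses["thigh"], poses["shank"],
                          calib_interval=calib)
        assert np.allclose(ja.hip_deg, 0.0, atol=1e-9)
        assert np.allclose(ja.knee_deg, 0.0, atol=1e-9)

    def test_pure_knee_flexion(self):
        n = 200
        knee = np.concatenate([np.zeros(n // 2), np.full(n // 2, 90.0)])
        poses, calib = self._streams(np.zeros(n), knee)
        ja = joint_angles(poses["waist"], poses["thigh"], poses["shank"],
                          calib_interval=calib)
        assert ja.knee_deg[-1] == pytest.approx(90.0, abs=1e-6)
        assert ja.hip_deg[-1] == pytest.approx(0.0, abs=1e-6)

    def test_sinusoidal_round_trip(self):
        angles = gen_angles(GaitProfile(n_cycles=3, fs=200), seed=4)
        poses, _, calib = gen_pose_streams(angles, seed=4)
        ja = joint_angles(poses["waist"], poses["thigh"], poses["shank"],
                          calib_interval=calib)
        m = ja.timestamps >= calib[1]
        assert np.sqrt(np.mean((ja.hip_deg[m] - angles.hip_deg) ** 2)) < 1e-6
        assert np.sqrt(np.mean((ja.knee_deg[m] - angles.knee_deg) ** 2)) < 1e-6
        assert (ja.knee_deg >= 0).all()

    def test_mounting_invariance(self):
        angles = gen_angles(GaitProfile(n_cycles=2, fs=100), seed=6)
        results = []
        for seed in (1, 2):
            poses, _, calib = gen_pose_streams(angles, seed=seed)
            ja = joint_angles(poses["waist"], poses["thigh"], poses["shank"],
                              calib_interval=calib)
            results.append((ja.hip_deg, ja.knee_deg))
        assert np.allclose(results[0][0], results[1][0], atol=1e-8)
        assert np.allclose(results[0][1], results[1][1], atol=1e-8)

    def test_hip_sign_flips_with_flexion_direction(self):
        angles = gen_angles(GaitProfile(n_cycles=2, fs=100,
                                        amplitude_variability=0.0), seed=8)
        flipped = gen_angles(GaitProfile(n_cycles=2, fs=100,
                                         amplitude_variability=0.0), seed=8)
        flipped.hip_deg = -flipped.hip_deg
        out = []
        for a in (angles, flipped):
            poses, _, calib = gen_pose_streams(a, seed=9)
            ja = joint_angles(poses["waist"], poses["thigh"], poses["shank"],
                              calib_interval=calib)
            out.append(ja.hip_deg[ja.timestamps >= calib[1]])
        assert np.allclose(out[0], -out[1], atol=1e-8)

    def test_misaligned_streams_rejected(self):
        n = 100
        poses, calib = self._streams(np.zeros(n), np.zeros(n))
        short = PoseStream("thigh", poses["thigh"].timestamps[:-1],
                           poses["thigh"].quaternions[:-1])
        with pytest.raises(ValueError):
            joint_angles(poses["waist"], short, poses["shank"],
                         calib_interval=calib)
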
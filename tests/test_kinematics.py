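"""Rigid registration and anatomical six-DOF decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from condylokit.core import AnatomicalFrame, RigidTransform
from condylokit.kinematics import (
    SixDOF,
    compose_six_dof,
    decompose_six_dof,
    register_rigid,
    relative_motion,
)


def random_transform(rng, max_angle=45.0, max_trans=20.0):
    d = SixDOF(*rng.uniform(-max_trans, max_trans, 3), *rng.uniform(-max_angle, max_angle, 3))
    return compose_six_dof(d), d


class TestRegistration:
    def test_identity_when_point_sets_coincide(self, rng):
        pts = rng.normal(scale=10, size=(50, 3))
        res = register_rigid(pts, pts)
        assert res.rms < 1e-12
        assert np.allclose(res.transform.matrix, np.eye(4), atol=1e-12)

    def test_correspondence_recovers_known_transform(self, rng):
        pts = rng.normal(scale=10, size=(100, 3))
        t, _ = random_transform(rng)
        res = register_rigid(pts, t.apply(pts), mode="correspondence")
        assert np.allclose(res.transform.matrix, t.matrix, atol=1e-9)
        assert res.rms < 1e-9

    def test_collinear_points_rejected(self):
        line = np.outer(np.arange(10.0), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="collinear"):
            register_rigid(line, line)

    def test_icp_recovers_noisy_motion(self, rng):
        """A 5 mm / 5 deg motion of a 0.1 mm noisy VOI is recovered to
        0.05 mm / 0.05 deg."""
        pts = rng.normal(scale=12, size=(2000, 3))
        R = Rotation.from_euler("xyz", [5, 0, 0], degrees=True).as_matrix()
        t_true = np.array([5.0, 0.0, 0.0])
        fixed = pts @ R.T + t_true
        noisy = pts + 0.1 * rng.normal(size=pts.shape)
        res = register_rigid(noisy, fixed, mode="icp")
        assert res.converged
        est = res.transform
        assert np.linalg.norm(est.translation - t_true) < 0.05
        cos = np.clip((np.trace(est.rotation @ R.T) - 1) / 2, -1, 1)
        assert np.degrees(np.arccos(cos)) < 0.05


class TestRelativeMotion:
    def test_equal_poses_give_identity(self, rng):
        t, _ = random_transform(rng)
        assert np.allclose(relative_motion(t, t).matrix, np.eye(4), atol=1e-12)

    def test_identity_first_pose_returns_second(self, rng):
        t, _ = random_transform(rng)
        assert np.allclose(relative_motion(RigidTransform.identity(), t).matrix, t.matrix)

    def test_matches_matrix_product_oracle(self, rng):
        tA, _ = random_transform(rng)
        tB, _ = random_transform(rng)
        expected = tB.matrix @ np.linalg.inv(tA.matrix)
        assert np.allclose(relative_motion(tA, tB).matrix, expected, atol=1e-12)


class TestSixDOF:
    def test_identity_transform_gives_zeros(self):
        d = decompose_six_dof(RigidTransform.identity())
        assert np.allclose(d.as_array(), 0)

    def test_pure_ap_translation(self):
        t = RigidTransform(np.eye(3), [0.0, 3.1, 0.0])
        d = decompose_six_dof(t)
        assert d.t_ap == pytest.approx(3.1)
        assert np.allclose([d.t_ml, d.t_si, d.pitch, d.roll, d.yaw], 0)

    def test_pitch_and_si_round_trip(self):
        d = SixDOF(pitch=-5.0, t_si=2.0)
        out = decompose_six_dof(compose_six_dof(d))
        assert np.allclose(out.as_array(), d.as_array(), atol=1e-12)

    def test_round_trip_1000_draws(self):
        """compose -> decompose is the identity to 1e-9 within +/-45 deg,
        +/-20 mm."""
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(1000):
            d = SixDOF(*rng.uniform(-20, 20, 3), *rng.uniform(-45, 45, 3))
            out = decompose_six_dof(compose_six_dof(d))
            worst = max(worst, float(np.abs(out.as_array() - d.as_array()).max()))
        assert worst < 1e-9

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-20, 20), min_size=3, max_size=3),
           st.lists(st.floats(-45, 45), min_size=3, max_size=3))
    def test_round_trip_property(self, trans, rots):
        d = SixDOF(*trans, *rots)
        out = decompose_six_dof(compose_six_dof(d))
        assert np.allclose(out.as_array(), d.as_array(), atol=1e-9)

    def test_mirrored_right_side_round_trip(self):
        d = SixDOF(1.5, -2.0, 0.7, 4.0, -3.0, 2.5, side="proximal_right", mirrored=True)
        t = compose_six_dof(d)
        out = decompose_six_dof(t, side="proximal_right")
        assert out.mirrored
        assert np.allclose(out.as_array(), d.as_array(), atol=1e-12)

    def test_mirror_consistency_across_sagittal_reflection(self, rng):
        """Reflecting geometry across the mid-sagittal plane and swapping
        side labels leaves the reported six DOF unchanged."""
        t, _ = random_transform(rng, max_angle=20, max_trans=8)
        S = np.diag([-1.0, 1.0, 1.0])
        m = np.eye(4)
        m[:3, :3] = S @ t.rotation @ S
        m[:3, 3] = S @ t.translation
        reflected = RigidTransform.from_matrix(m)
        d_left = decompose_six_dof(t, side="proximal_left")
        d_right = decompose_six_dof(reflected, side="proximal_right")
        assert np.allclose(d_left.as_array(), d_right.as_array(), atol=1e-9)

    def test_gimbal_range_violation_raises(self):
        # a 95-degree rotation re-expresses with |pitch|,|yaw| near 180
        R = Rotation.from_euler("Y", -95, degrees=True).as_matrix()
        with pytest.raises(ValueError, match="Euler range"):
            decompose_six_dof(RigidTransform(R, np.zeros(3)))

    def test_polar_projection_stability(self, rng):
        """A small rotation perturbation (norm <= 1e-3) shifts decomposed
        angles by well under 0.1 degree after projection."""
        t, d = random_transform(rng, max_angle=30, max_trans=5)
        noise = 1e-3 * rng.normal(size=(3, 3))
        noise *= 1e-3 / max(np.linalg.norm(noise), 1e-12)
        perturbed = RigidTransform(t.rotation + noise, t.translation)
        d2 = decompose_six_dof(perturbed)
        assert np.abs(d2.as_array()[3:] - d.as_array()[3:]).max() < 0.1

    def test_custom_frame_translation_projection(self):
        frame = AnatomicalFrame(
            origin=np.array([1.0, 2.0, 3.0]),
            ml=np.array([0.0, 1.0, 0.0]),
            ap=np.array([0.0, 0.0, 1.0]),
            si=np.array([1.0, 0.0, 0.0]),
        )
        d = SixDOF(t_ml=2.0, t_ap=-1.0, t_si=0.5, pitch=7.0)
        out = decompose_six_dof(compose_six_dof(d, frame), frame)
        assert np.allclose(out.as_array(), d.as_array(), atol=1e-10)

    def test_transform_json_round_trip(self, rng):
        t, _ = random_transform(rng)
        assert np.allclose(RigidTransform.from_json(t.to_json()).matrix, t.matrix)
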
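"""Rigid pose fitting, Cardan angle decomposition, ROM, angular velocity."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from kinerisk.errors import DegenerateGeometryError, KineriskError
from kinerisk.kinematics import (
    SegmentPoseSeries,
    angular_velocity,
    compute_joint_angles,
    compute_rom,
    fit_segment_pose,
)

TEMPLATE = {
    "A": np.array([0.0, 0.0, 0.0]),
    "B": np.array([100.0, 0.0, 0.0]),
    "C": np.array([0.0, 100.0, 0.0]),
    "D": np.array([0.0, 0.0, 100.0]),
}


def _observe(rotation, translation, noise=None, rng=None):
    obs = {}
    for label, p in TEMPLATE.items():
        q = rotation @ p + translation
        if noise:
            q = q + rng.normal(0.0, noise, 3)
        obs[label] = q
    return obs


class TestPoseFit:
    def test_identity(self):
        fit = fit_segment_pose(dict(TEMPLATE), TEMPLATE)
        np.testing.assert_allclose(fit.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(fit.translation, 0.0, atol=1e-12)
        assert fit.residual_rms < 1e-12

    def test_recovers_known_transform(self):
        r = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        t = np.array([100.0, 0.0, 0.0])
        fit = fit_segment_pose(_observe(r, t), TEMPLATE)
        np.testing.assert_allclose(fit.rotation, r, atol=1e-12)
        np.testing.assert_allclose(fit.translation, t, atol=1e-10)
        assert fit.residual_rms < 1e-10

    def test_random_transforms_recovered_exactly(self):
        """Noise-free fits must reproduce the generating transform: the
        exact rigid alignment is unique for >=3 non-collinear points."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            r = Rotation.random(random_state=rng).as_matrix()
            t = rng.normal(0.0, 500.0, 3)
            fit = fit_segment_pose(_observe(r, t), TEMPLATE)
            assert fit.residual_rms < 1e-9
            np.testing.assert_allclose(fit.rotation, r, atol=1e-9)
        # proper rotation, not a reflection
        assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_noisy_markers_small_residual_and_rotation_error(self):
        rng = np.random.default_rng(7)
        residuals, angles = [], []
        for _ in range(50):
            fit = fit_segment_pose(
                _observe(np.eye(3), np.zeros(3), noise=1.0, rng=rng), TEMPLATE
            )
            residuals.append(fit.residual_rms)
            angles.append(
                np.degrees(np.arccos(np.clip((np.trace(fit.rotation) - 1) / 2, -1, 1)))
            )
        assert np.mean(residuals) <= 2.0
        assert np.mean(angles) < 1.0
        assert np.max(angles) < 2.0

    def test_collinear_template_degenerate(self):
        tmpl = {"A": [0.0, 0, 0], "B": [1.0, 0, 0], "C": [2.0, 0, 0]}
        obs = {k: np.asarray(v) for k, v in tmpl.items()}
        with pytest.raises(DegenerateGeometryError):
            fit_segment_pose(obs, tmpl)

    def test_fewer_than_three_markers_rejected(self):
        with pytest.raises(KineriskError, match=">=3"):
            fit_segment_pose({"A": TEMPLATE["A"], "B": TEMPLATE["B"]}, TEMPLATE)


def _pose_series(rot_matrices, frame_rate=200.0):
    n = len(rot_matrices)
    return SegmentPoseSeries(
        "seg",
        np.array(rot_matrices),
        np.zeros((n, 3)),
        np.zeros(n),
        np.ones(n, dtype=bool),
        frame_rate,
    )


class TestJointAngles:
    def test_identical_orientations_give_zero(self):
        eye = [np.eye(3)] * 4
        ja = compute_joint_angles(_pose_series(eye), _pose_series(eye))
        np.testing.assert_allclose(ja.angles, 0.0, atol=1e-10)

    def test_single_axis_flexion(self):
        parent = _pose_series([np.eye(3)])
        child = _pose_series(
            [Rotation.from_euler("x", 30, degrees=True).as_matrix()]
        )
        ja = compute_joint_angles(parent, child)
        np.testing.assert_allclose(ja.angles[0], [30.0, 0.0, 0.0], atol=1e-10)

    def test_decompose_recompose_identity(self):
        """Recomposing the three angles in sequence reproduces R_rel."""
        rng = np.random.default_rng(99)
        rels, parents = [], []
        for _ in range(300):
            rp = Rotation.random(random_state=rng)
            rrel = Rotation.random(random_state=rng)
            parents.append(rp.as_matrix())
            rels.append(rrel.as_matrix())
        parent = _pose_series(parents)
        child = _pose_series([p @ r for p, r in zip(parents, rels)])
        ja = compute_joint_angles(parent, child)
        for f, rrel in enumerate(rels):
            middle = abs(abs(ja.angles[f, 1]) - 90.0)
            if middle < 1.0:
                assert ja.gimbal_flags[f]
                continue
            # unwrapping may shift components by 360 deg; recompose modulo that
            recomposed = Rotation.from_euler(
                "XYZ", ja.angles[f], degrees=True
            ).as_matrix()
            np.testing.assert_allclose(recomposed, rrel, atol=1e-9)

    def test_continuity_no_jumps_across_wraparound(self):
        angles = np.linspace(170.0, 190.0, 21)  # crosses +180
        parent = _pose_series([np.eye(3)] * 21)
        child = _pose_series(
            [Rotation.from_euler("z", a, degrees=True).as_matrix() for a in angles]
        )
        ja = compute_joint_angles(parent, child)
        assert np.all(np.abs(np.diff(ja.rotation)) < 180.0)
        np.testing.assert_allclose(ja.rotation, angles, atol=1e-9)


class TestRom:
    def test_constant_sequence_zero(self):
        assert compute_rom(np.full(10, 42.0)) == 0.0

    def test_span(self):
        assert compute_rom(np.array([-10.0, 50.0, 119.0])) == pytest.approx(129.0)

    def test_shift_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 30, 100)
        assert compute_rom(x + 17.3) == pytest.approx(compute_rom(x))

    def test_empty_rejected(self):
        with pytest.raises(KineriskError):
            compute_rom(np.array([]))


class TestAngularVelocity:
    def test_constant_angle_zero_velocity(self):
        res = angular_velocity(np.full(10, 5.0), 200.0)
        np.testing.assert_allclose(res.omega, 0.0)
        assert res.peak_speed == 0.0

    def test_linear_ramp_slope(self):
        angles = 10.0 * np.arange(20)
        res = angular_velocity(angles, 200.0)
        np.testing.assert_allclose(res.omega, 2000.0)

    def test_sinusoid_peak_closed_form(self):
        fs, f, amp = 200.0, 2.0, 90.0
        t = np.arange(int(fs)) / fs
        res = angular_velocity(amp * np.sin(2 * np.pi * f * t), fs)
        assert res.peak_speed == pytest.approx(2 * np.pi * f * amp, rel=0.01)
        assert res.peak_deceleration > 0.0

    def test_too_short_rejected(self):
        with pytest.raises(KineriskError):
            angular_velocity(np.array([1.0, 2.0]), 200.0)
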
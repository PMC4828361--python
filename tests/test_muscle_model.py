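"""Muscle path length, rest-length normalization, speed, work patterns."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from kinerisk.errors import KineriskError
from kinerisk.model import MusclePathDefinition
from kinerisk.muscle_model import (
    classify_work_pattern,
    compute_rest_length,
    lengthening_speed,
    muscle_length,
    normalized_lengthening,
)

IDENTITY_POSE = (np.eye(3), np.zeros(3))


class TestMuscleLength:
    def test_two_points_on_static_segment(self):
        path = MusclePathDefinition("m", [("seg", [0, 0, 0]), ("seg", [0, 0, 100])])
        assert muscle_length(path, {"seg": IDENTITY_POSE}) == pytest.approx(100.0)

    def test_collinear_via_point_equals_direct_distance(self):
        direct = MusclePathDefinition("d", [("seg", [0, 0, 0]), ("seg", [0, 0, 100])])
        via = MusclePathDefinition(
            "v", [("seg", [0, 0, 0]), ("seg", [0, 0, 40]), ("seg", [0, 0, 100])]
        )
        poses = {"seg": IDENTITY_POSE}
        assert muscle_length(via, poses) == pytest.approx(muscle_length(direct, poses))

    def test_hinge_matches_law_of_cosines(self):
        """Two-point path across a hinge: the planar two-link closed form.

        Origin at distance r1 from the joint centre on the fixed parent,
        insertion at r2 on the child; a +theta hinge rotation about x closes
        the neutral 90-degree separation, so
        L = sqrt(r1^2 + r2^2 - 2 r1 r2 cos(phi0 - theta)).
        """
        r1, r2 = 100.0, 150.0
        path = MusclePathDefinition(
            "m", [("parent", [0, 0, r1]), ("child", [0, r2, 0])]
        )  # 90 deg apart at neutral
        phi0 = np.pi / 2
        for theta_deg in np.linspace(-80.0, 80.0, 17):
            rot = Rotation.from_euler("x", theta_deg, degrees=True).as_matrix()
            poses = {"parent": IDENTITY_POSE, "child": (rot, np.zeros(3))}
            theta = np.radians(theta_deg)
            expected = np.sqrt(r1**2 + r2**2 - 2 * r1 * r2 * np.cos(phi0 - theta))
            assert muscle_length(path, poses) == pytest.approx(expected, abs=1e-6)

    def test_polyline_never_shorter_than_endpoints(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            pts = rng.normal(0.0, 100.0, size=(4, 3))
            path = MusclePathDefinition("m", [("seg", p) for p in pts])
            direct = MusclePathDefinition("d", [("seg", pts[0]), ("seg", pts[-1])])
            poses = {"seg": IDENTITY_POSE}
            assert muscle_length(path, poses) >= muscle_length(direct, poses) - 1e-9

    def test_invariant_under_global_rigid_transform(self):
        rng = np.random.default_rng(8)
        path = MusclePathDefinition(
            "m", [("a", [10, 0, 50]), ("b", [0, 30, -60]), ("a", [5, 5, 5])]
        )
        pose_a = (Rotation.random(random_state=rng).as_matrix(), rng.normal(0, 100, 3))
        pose_b = (Rotation.random(random_state=rng).as_matrix(), rng.normal(0, 100, 3))
        base = muscle_length(path, {"a": pose_a, "b": pose_b})
        g_r = Rotation.random(random_state=rng).as_matrix()
        g_t = rng.normal(0, 500, 3)
        moved = {
            name: (g_r @ r, g_r @ t + g_t)
            for name, (r, t) in {"a": pose_a, "b": pose_b}.items()
        }
        assert muscle_length(path, moved) == pytest.approx(base, abs=1e-9)

    def test_missing_segment_pose_rejected(self):
        path = MusclePathDefinition("m", [("a", [0, 0, 0]), ("b", [0, 0, 1])])
        with pytest.raises(KineriskError, match="'b'"):
            muscle_length(path, {"a": IDENTITY_POSE})


class TestRestLengthAndNormalization:
    def test_neutral_frame_is_exactly_100_pct(self, model_muscles):
        model, muscles = model_muscles
        neutral = model.neutral_poses()
        for muscle in muscles:
            rest = compute_rest_length(muscle, neutral)
            length = muscle_length(muscle, neutral)
            assert normalized_lengthening(np.array([length]), rest)[0] == pytest.approx(100.0)

    def test_subject_scaling_leaves_normalized_unchanged(self):
        path = MusclePathDefinition("m", [("a", [0, 0, 100]), ("b", [0, 120, 0])])
        rot = Rotation.from_euler("x", 40, degrees=True).as_matrix()
        poses = {"a": IDENTITY_POSE, "b": (rot, np.zeros(3))}
        rest = muscle_length(path, {"a": IDENTITY_POSE, "b": IDENTITY_POSE})
        bent = muscle_length(path, poses)
        scaled_path = MusclePathDefinition(
            "m", [(seg, 1.1 * p) for seg, p in path.points]
        )
        rest_s = muscle_length(scaled_path, {"a": IDENTITY_POSE, "b": IDENTITY_POSE})
        bent_s = muscle_length(scaled_path, poses)
        assert rest_s == pytest.approx(1.1 * rest)
        assert 100 * bent_s / rest_s == pytest.approx(100 * bent / rest)

    def test_normalized_values(self):
        out = normalized_lengthening(np.array([100.0, 135.0, 120.0]), 100.0)
        np.testing.assert_allclose(out, [100.0, 135.0, 120.0])

    def test_nonpositive_rest_rejected(self):
        with pytest.raises(KineriskError):
            normalized_lengthening(np.array([1.0]), 0.0)


class TestLengtheningSpeed:
    def test_constant_length_zero(self):
        speed, peak = lengthening_speed(np.full(10, 300.0), 200.0)
        np.testing.assert_allclose(speed, 0.0)
        assert peak == 0.0

    def test_linear_2mm_per_frame_at_200hz(self):
        lengths = 300.0 + 2.0 * np.arange(20)
        speed, peak = lengthening_speed(lengths, 200.0)
        np.testing.assert_allclose(speed, 0.4)
        assert peak == pytest.approx(0.4)

    def test_sinusoid_peak_closed_form(self):
        fs, f, amp = 200.0, 2.0, 25.0
        t = np.arange(int(fs)) / fs
        lengths = 300.0 + amp * np.sin(2 * np.pi * f * t)
        _, peak = lengthening_speed(lengths, fs)
        assert peak == pytest.approx(2 * np.pi * f * amp / 1000.0, rel=0.01)

    def test_too_few_frames_rejected(self):
        with pytest.raises(KineriskError):
            lengthening_speed(np.array([1.0, 2.0]), 200.0)


class TestWorkPattern:
    def test_monotone_increase_all_lengthening(self):
        lengths = 300.0 + 2.0 * np.arange(10)
        assert set(classify_work_pattern(lengths, 200.0)) == {"lengthening"}

    def test_constant_all_isometric(self):
        assert set(classify_work_pattern(np.full(10, 300.0), 200.0)) == {"isometric"}

    def test_triangle_wave_switches_at_apex(self):
        up = 300.0 + 5.0 * np.arange(10)
        tri = np.concatenate([up, up[-2::-1]])
        labels = classify_work_pattern(tri, 200.0)
        switch = int(np.argmax(labels == "shortening"))
        assert abs(switch - 10) <= 1
        assert set(labels[:8]) == {"lengthening"}
        assert set(labels[-8:]) == {"shortening"}
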
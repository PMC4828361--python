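"""Risk threshold, muscle ranking, impact-like detection, pitch phases."""

import numpy as np
import pytest

from kinerisk.errors import KineriskError, SegmentationError
from kinerisk.examples import (
    FAN_VS_AXE_MUSCLE_LENGTHENING,
    INSTEP_KICK_MUSCLE_LENGTHENING,
)
from kinerisk.kinematics import JointAngleSeries
from kinerisk.risk_analysis import (
    PITCH_PHASE_NAMES,
    PitchPhaseSegmentation,
    assess_risk_value,
    detect_impact_like,
    rank_muscles,
    segment_pitch_phases,
)


class TestThreshold:
    def test_severe_over_lengthening_flagged(self):
        assert assess_risk_value("adductor_magnus", 174.6).at_risk

    def test_below_threshold_not_flagged(self):
        assert not assess_risk_value("rectus_femoris", 112.8).at_risk

    def test_exact_boundary_not_flagged(self):
        # the criterion is strictly ">120%"
        assert not assess_risk_value("edge", 120.0).at_risk
        assert assess_risk_value("edge", 120.0 + 1e-9).at_risk

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(17)
        values = rng.uniform(90.0, 200.0, 30)
        flagged_low = {
            i for i, v in enumerate(values) if assess_risk_value(str(i), v, 110.0).at_risk
        }
        flagged_high = {
            i for i, v in enumerate(values) if assess_risk_value(str(i), v, 140.0).at_risk
        }
        assert flagged_high <= flagged_low


class TestRankMuscles:
    def test_instep_kick_means_flag_three_adductor_group_muscles(self):
        assessments = [
            assess_risk_value(name, mean)
            for name, (mean, _) in INSTEP_KICK_MUSCLE_LENGTHENING.items()
        ]
        ordered, flagged = rank_muscles(assessments)
        assert {a.muscle for a in flagged} == {
            "adductor_magnus",
            "gracilis",
            "semimembranosus",
        }
        values = [a.max_normalized_pct for a in ordered]
        assert values == sorted(values, reverse=True)

    def test_axe_kick_means_flag_four_muscles(self):
        assessments = [
            assess_risk_value(name, axe_mean)
            for name, (_, (axe_mean, _)) in FAN_VS_AXE_MUSCLE_LENGTHENING.items()
        ]
        _, flagged = rank_muscles(assessments)
        assert {a.muscle for a in flagged} == {
            "biceps_femoris",
            "adductor_magnus",
            "gracilis",
            "semimembranosus",
        }

    def test_all_below_threshold_empty_flagged(self):
        assessments = [assess_risk_value(f"m{i}", 100.0 + i) for i in range(5)]
        _, flagged = rank_muscles(assessments)
        assert flagged == []

    def test_output_is_permutation_of_input(self):
        rng = np.random.default_rng(3)
        assessments = [
            assess_risk_value(f"m{i}", v) for i, v in enumerate(rng.uniform(80, 220, 12))
        ]
        ordered, _ = rank_muscles(assessments)
        assert sorted(a.muscle for a in ordered) == sorted(a.muscle for a in assessments)

    def test_empty_input_rejected(self):
        with pytest.raises(KineriskError):
            rank_muscles([])


class TestImpactLike:
    FS = 200.0

    def test_constant_low_speed_no_events(self):
        assert detect_impact_like(np.full(100, 0.05), self.FS) == []

    def test_step_rise_during_lengthening_one_event(self):
        # baseline 0.05 m/s, climbing to 0.6 m/s over 60 ms (12 frames)
        speed = np.full(200, 0.05)
        speed[100:112] = np.linspace(0.05, 0.6, 12)
        speed[112:130] = 0.6
        speed[130:] = 0.05
        events = detect_impact_like(speed, self.FS)
        assert len(events) == 1
        ev = events[0]
        assert ev.start_frame <= 101 and 105 <= ev.end_frame <= 115
        assert ev.speed_rise_m_s2 > 0

    def test_same_jump_during_shortening_no_event(self):
        speed = np.full(200, -0.05)
        speed[100:112] = np.linspace(-0.05, -0.6, 12)
        speed[112:] = -0.6
        assert detect_impact_like(speed, self.FS) == []

    def test_slow_rise_outside_window_no_event(self):
        # same magnitude of rise but spread over 2 s: the climb from the
        # median to 3x the median takes far longer than the 100 ms window
        speed = np.full(700, 0.05)
        speed[100:500] = np.linspace(0.05, 0.6, 400)
        speed[500:550] = 0.6
        speed[550:] = 0.05
        assert detect_impact_like(speed, self.FS, rise_window_ms=100.0) == []

    def test_all_zero_speed_no_events_no_error(self):
        assert detect_impact_like(np.zeros(100), self.FS) == []

    def test_monotone_decreasing_never_fires(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            speed = np.sort(rng.uniform(0.0, 1.0, 150))[::-1]
            assert detect_impact_like(speed, self.FS) == []


def _angle_series(rotation_deg, fs=200.0):
    angles = np.zeros((len(rotation_deg), 3))
    angles[:, 2] = rotation_deg
    return JointAngleSeries("shoulder_r", angles, fs)


class TestPitchSegmentation:
    def test_generator_round_trip_within_two_frames(self, trials, analyses):
        _, _, truth = trials["pitch"]
        seg = analyses["pitch"].segmentation
        assert seg is not None
        for name, frame in truth.event_frames.items():
            assert abs(seg.events[name] - frame) <= 2, name

    def test_monotone_rotation_rejected(self):
        n = 200
        rot = np.linspace(0.0, 150.0, n)  # no interior extremum
        foot = np.concatenate([np.linspace(80, 300, 50), np.linspace(300, 80, 50),
                               np.full(100, 80.0)])
        hand = np.abs(np.sin(np.linspace(0, 3, n)))
        with pytest.raises(SegmentationError, match="rotation"):
            segment_pitch_phases(_angle_series(rot), hand, foot)

    def test_phases_partition_the_trial(self, analyses):
        seg = analyses["pitch"].segmentation
        phases = seg.phases
        assert tuple(phases) == PITCH_PHASE_NAMES
        bounds = list(phases.values())
        assert bounds[0][0] == seg.events["initial_position"]
        assert bounds[-1][1] == seg.events["fielding_position"]
        for (_, end), (start, _) in zip(bounds, bounds[1:]):
            assert end == start  # contiguous, non-overlapping

    def test_non_increasing_events_rejected(self):
        events = dict(
            zip(
                (
                    "initial_position", "balance_point", "foot_contact",
                    "max_shoulder_external_rotation", "ball_release",
                    "max_shoulder_internal_rotation", "fielding_position",
                ),
                (0, 50, 40, 60, 70, 80, 100),
            )
        )
        with pytest.raises(SegmentationError, match="increasing"):
            PitchPhaseSegmentation(events, 200.0)
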
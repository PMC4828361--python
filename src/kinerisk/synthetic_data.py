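"""Synthetic marker trajectories with known ground truth.

No capture recordings accompany the analyses this package reimplements, so
every pipeline stage is validated against motions generated here: joint
angle curves are prescribed as piecewise-cubic (PCHIP) control points,
composed down the skeleton's joint tree by forward kinematics, and the
segment marker templates are transformed to global coordinates. Seeded
isotropic Gaussian noise and occlusion windows are applied last; the
ground-truth payload carries the noise-free angles, muscle lengths and (for
pitch scripts) event frames, so it is a true independent oracle for the
marker-fitting pipeline.

PCHIP interpolation never overshoots its control points, so a preset's
prescribed excursion (max minus min control value) is exactly the ROM of
the generated angle curve.

Preset excursions default to the group means reported for each skill
(instep kick, fan kick, axe kick, baseball pitch); they demonstrate the
study conditions rather than reproduce any subject.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.spatial.transform import Rotation

from .errors import KineriskError
from .io_formats import MarkerFrameSeries
from .kinematics import SegmentPoseSeries
from .model import MusclePathDefinition, SkeletonModel, default_model
from .muscle_model import compute_rest_length, muscle_length_series

__all__ = [
    "MotionScript",
    "GroundTruth",
    "generate_motion",
    "preset_script",
    "forward_kinematics",
    "PRESET_SKILLS",
]

COMPONENTS = ("flexion_extension", "abduction_adduction", "rotation")

Curve = list[tuple[float, float]]  # (time s, angle deg) control points


@dataclass
class MotionScript:
    """A prescribed motion: per-joint angle curves plus noise/occlusion spec."""

    skill: str
    duration: float
    frame_rate: float = 200.0
    curves: dict[str, dict[str, Curve]] = field(default_factory=dict)
    noise_sd_mm: float = 0.0
    occlusions: list[tuple[str, int, int]] = field(default_factory=list)
    seed: int = 0
    event_frames: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.noise_sd_mm < 0:
            raise KineriskError("noise SD must be >= 0")
        if self.duration <= 0 or self.frame_rate <= 0:
            raise KineriskError("duration and frame rate must be > 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate)) + 1

    def angles_for(self, joint: str) -> np.ndarray:
        """Evaluate the joint's three angle components on the frame grid."""
        t = np.arange(self.n_frames) / self.frame_rate
        out = np.zeros((self.n_frames, 3))
        spec = self.curves.get(joint, {})
        for c, name in enumerate(COMPONENTS):
            pts = spec.get(name)
            if not pts:
                continue
            pts = sorted(pts)
            times = np.array([p[0] for p in pts], dtype=float)
            vals = np.array([p[1] for p in pts], dtype=float)
            if len(pts) == 1:
                out[:, c] = vals[0]
            else:
                tt = np.clip(t, times[0], times[-1])  # hold beyond the ends
                out[:, c] = PchipInterpolator(times, vals)(tt)
        return out

    def prescribed_rom(self) -> dict[str, np.ndarray]:
        """max - min of each joint's prescribed angle components (degrees)."""
        return {
            joint: np.ptp(self.angles_for(joint), axis=0) for joint in self.curves
        }


@dataclass
class GroundTruth:
    """Noise-free oracle payload emitted alongside a generated series."""

    joint_angles: dict[str, np.ndarray]  # joint -> (n, 3) degrees
    muscle_lengths_mm: dict[str, np.ndarray]
    rest_lengths_mm: dict[str, float]
    frame_rate: float
    event_frames: dict[str, int] | None = None

    def normalized_pct(self, muscle: str) -> np.ndarray:
        return 100.0 * self.muscle_lengths_mm[muscle] / self.rest_lengths_mm[muscle]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "frame_rate": self.frame_rate,
            "joint_angles_deg": {k: v.tolist() for k, v in self.joint_angles.items()},
            "muscle_lengths_mm": {
                k: v.tolist() for k, v in self.muscle_lengths_mm.items()
            },
            "rest_lengths_mm": self.rest_lengths_mm,
            "event_frames": self.event_frames,
        }
        Path(path).write_text(json.dumps(payload) + "\n")


def forward_kinematics(
    model: SkeletonModel, joint_angles: dict[str, np.ndarray], frame_rate: float
) -> dict[str, SegmentPoseSeries]:
    """Compose segment poses down the joint tree from prescribed angles.

    ``joint_angles`` maps joint name (as configured per child segment) to an
    ``(n, 3)`` array of Cardan angles in degrees, in each joint's configured
    sequence.
    """
    n = next(iter(joint_angles.values())).shape[0] if joint_angles else 1
    poses: dict[str, SegmentPoseSeries] = {}
    for name in model.topological_order:
        seg = model.segments[name]
        if seg.parent is None:
            rot = np.tile(np.eye(3), (n, 1, 1))
            trans = np.tile(seg.origin_in_parent, (n, 1))
        else:
            joint = seg.joint_name or name
            if joint not in joint_angles:
                raise KineriskError(f"script is missing joint {joint!r}")
            ang = np.asarray(joint_angles[joint], dtype=float)
            r_joint = Rotation.from_euler(
                seg.euler_sequence, ang, degrees=True
            ).as_matrix()
            if r_joint.ndim == 2:
                r_joint = r_joint[None]
            parent = poses[seg.parent]
            rot = np.einsum("nij,njk->nik", parent.rotations, r_joint)
            trans = parent.translations + np.einsum(
                "nij,j->ni", parent.rotations, seg.origin_in_parent
            )
        poses[name] = SegmentPoseSeries(
            name,
            rot,
            trans,
            np.zeros(n),
            np.ones(n, dtype=bool),
            frame_rate,
        )
    return poses


def generate_motion(
    script: MotionScript,
    model: SkeletonModel,
    muscles: list[MusclePathDefinition] | None = None,
) -> tuple[MarkerFrameSeries, GroundTruth]:
    """Generate a labeled marker series plus its noise-free ground truth.

    Every joint of the model's tree must be covered by the script (a curve
    mapping may be empty, meaning the joint holds its neutral angles, but
    the key must be present). Markers are emitted once each, from their
    owner segment; isotropic Gaussian noise (seeded) and occlusions are
    applied after the noise-free ground truth is recorded.
    """
    joint_names = [j for j, _, _ in model.joints()]
    for joint in joint_names:
        if joint not in script.curves:
            raise KineriskError(f"script is missing joint {joint!r}")
    angles = {joint: script.angles_for(joint) for joint in joint_names}
    poses = forward_kinematics(model, angles, script.frame_rate)
    n = script.n_frames

    owner = model.marker_owner()
    labels = model.marker_labels
    positions = np.empty((len(labels), n, 3))
    for m, label in enumerate(labels):
        seg = model.segments[owner[label]]
        ps = poses[seg.name]
        local = seg.markers[label]
        positions[m] = np.einsum("nij,j->ni", ps.rotations, local) + ps.translations

    if muscles is None:
        muscles = []
    neutral = model.neutral_poses()
    rest = {mu.name: compute_rest_length(mu, neutral) for mu in muscles}
    lengths = {
        mu.name: muscle_length_series(mu, poses, rest[mu.name]).lengths_mm
        for mu in muscles
    }
    truth = GroundTruth(
        joint_angles=angles,
        muscle_lengths_mm=lengths,
        rest_lengths_mm=rest,
        frame_rate=script.frame_rate,
        event_frames=script.event_frames,
    )

    rng = np.random.default_rng(script.seed)
    if script.noise_sd_mm > 0:
        positions = positions + rng.normal(0.0, script.noise_sd_mm, positions.shape)
    missing = np.zeros((len(labels), n), dtype=bool)
    for label, start, end in script.occlusions:
        if label not in labels:
            raise KineriskError(f"occlusion references unknown marker {label!r}")
        missing[labels.index(label), start:end] = True
    positions = np.where(missing[:, :, None], np.nan, positions)
    series = MarkerFrameSeries(labels, script.frame_rate, positions, missing)
    return series, truth


# ---------------------------------------------------------------------------
# Skill presets
# ---------------------------------------------------------------------------

#: Default excursion parameters per skill. Kick excursions are the reported
#: per-skill group means (degrees); durations reflect that the axe kick is
#: performed in roughly half the time of the fan kick.
PRESET_PARAMS: dict[str, dict] = {
    "instep_kick": dict(
        duration=1.2,
        hip_flexion_excursion=129.0,
        hip_abduction_excursion=26.0,
        hip_rotation_excursion=17.0,
        knee_flexion_excursion=113.0,
        knee_abduction_excursion=23.0,
        knee_rotation_excursion=19.0,
        hyperextension_fraction=0.23,  # tension-arc backswing share of hip ROM
    ),
    "fan_kick": dict(
        duration=1.6,
        hip_flexion_excursion=146.3,
        hip_abduction_excursion=87.8,
        hip_rotation_excursion=54.1,
        knee_flexion_excursion=108.9,
        knee_abduction_excursion=27.4,
        knee_rotation_excursion=28.2,
        hyperextension_fraction=0.05,
    ),
    "axe_kick": dict(
        duration=0.8,
        hip_flexion_excursion=162.2,
        hip_abduction_excursion=51.6,
        hip_rotation_excursion=57.9,
        knee_flexion_excursion=65.3,
        knee_abduction_excursion=28.8,
        knee_rotation_excursion=21.5,
        hyperextension_fraction=0.08,
    ),
    "pitch": dict(
        duration=2.0,
        shoulder_abduction=-75.0,
        shoulder_external_rotation_max=170.0,
        shoulder_internal_rotation_min=-90.0,
        elbow_flexion=90.0,
        stride_hip_flexion=55.0,
        stride_knee_flexion=-40.0,
        # event times as fractions of the trial
        balance_fraction=0.25,
        foot_contact_fraction=0.4,
        mer_fraction=0.55,
        release_fraction=0.6,
        mir_fraction=0.65,
    ),
}

PRESET_SKILLS = tuple(PRESET_PARAMS)

SCRIPT_FIELDS = {"duration", "frame_rate", "noise_sd_mm", "occlusions", "seed"}


def _zero_curves(model: SkeletonModel) -> dict[str, dict[str, Curve]]:
    return {joint: {} for joint, _, _ in model.joints()}


def _snap(t: float, frame_rate: float) -> float:
    """Snap a knot time onto the frame grid so curve extrema land exactly
    on sampled frames (PCHIP extrema sit at control points)."""
    return round(t * frame_rate) / frame_rate


def _kick_script(skill: str, p: dict, model: SkeletonModel, script_kw: dict) -> MotionScript:
    d = p["duration"]
    fs = script_kw["frame_rate"]
    s = lambda frac: _snap(frac * d, fs)
    curves = _zero_curves(model)
    hyper = p["hyperextension_fraction"]
    flex_min = -hyper * p["hip_flexion_excursion"]
    flex_max = (1.0 - hyper) * p["hip_flexion_excursion"]
    kexc = p["knee_flexion_excursion"]
    curves["hip_r"] = {
        "flexion_extension": [
            (0.0, 0.0),
            (s(0.35), flex_min),
            (s(0.72), flex_max),
            (d, 0.4 * flex_max),
        ],
        "abduction_adduction": [
            (0.0, 0.0),
            (s(0.55), -p["hip_abduction_excursion"]),
            (d, -0.2 * p["hip_abduction_excursion"]),
        ],
        "rotation": [
            (0.0, 0.0),
            (s(0.6), p["hip_rotation_excursion"]),
            (d, 0.3 * p["hip_rotation_excursion"]),
        ],
    }
    curves["knee_r"] = {
        "flexion_extension": [
            (0.0, -5.0),
            (s(0.55), -5.0 - kexc),
            (s(0.9), -5.0),
            (d, -10.0),
        ],
        "abduction_adduction": [
            (0.0, 0.0),
            (s(0.5), p["knee_abduction_excursion"]),
            (d, 0.2 * p["knee_abduction_excursion"]),
        ],
        "rotation": [
            (0.0, 0.0),
            (s(0.6), p["knee_rotation_excursion"]),
            (d, 0.2 * p["knee_rotation_excursion"]),
        ],
    }
    return MotionScript(skill=skill, curves=curves, **script_kw)


def _pitch_script(p: dict, model: SkeletonModel, script_kw: dict) -> MotionScript:
    d = p["duration"]
    fs = script_kw["frame_rate"]
    t_bal = _snap(p["balance_fraction"] * d, fs)
    t_fc = _snap(p["foot_contact_fraction"] * d, fs)
    t_mer = _snap(p["mer_fraction"] * d, fs)
    t_mir = _snap(p["mir_fraction"] * d, fs)
    curves = _zero_curves(model)
    # lead (left) leg: lift to the balance point, plant sharply at contact
    curves["hip_l"] = {
        "flexion_extension": [
            (0.0, 0.0),
            (t_bal, p["stride_hip_flexion"]),
            (t_fc - 0.01 * d, 0.11 * p["stride_hip_flexion"]),
            (t_fc, 0.0),
            (d, 0.0),
        ]
    }
    curves["knee_l"] = {
        "flexion_extension": [
            (0.0, 0.0),
            (t_bal, p["stride_knee_flexion"]),
            (t_fc - 0.01 * d, 0.11 * p["stride_knee_flexion"]),
            (t_fc, 0.0),
            (d, 0.0),
        ]
    }
    # throwing (right) arm
    curves["shoulder_r"] = {
        "abduction_adduction": [
            (0.0, 0.0),
            (t_fc, p["shoulder_abduction"]),
            (d, p["shoulder_abduction"]),
        ],
        "rotation": [
            (0.0, 0.0),
            (t_fc, 0.0),
            (t_mer, p["shoulder_external_rotation_max"]),
            (t_mir, p["shoulder_internal_rotation_min"]),
            (t_mir + 0.15 * d, 0.67 * p["shoulder_internal_rotation_min"]),
            (d, 0.67 * p["shoulder_internal_rotation_min"]),
        ],
    }
    curves["elbow_r"] = {
        "flexion_extension": [
            (0.0, 0.0),
            (t_bal, 10.0),
            (t_fc, p["elbow_flexion"]),
            (d, p["elbow_flexion"]),
        ]
    }
    script = MotionScript(skill="pitch", curves=curves, **script_kw)
    fs = script.frame_rate
    script.event_frames = {
        "initial_position": 0,
        "balance_point": int(round(t_bal * fs)),
        "foot_contact": int(round(t_fc * fs)),
        "max_shoulder_external_rotation": int(round(t_mer * fs)),
        "ball_release": int(round(p["release_fraction"] * d * fs)),
        "max_shoulder_internal_rotation": int(round(t_mir * fs)),
        "fielding_position": script.n_frames - 1,
    }
    return script


def preset_script(
    skill: str,
    overrides: dict | None = None,
    model: SkeletonModel | None = None,
) -> MotionScript:
    """A curated script for one of the studied skills.

    ``overrides`` may adjust both excursion parameters (see
    :data:`PRESET_PARAMS`) and script fields (``duration``, ``frame_rate``,
    ``noise_sd_mm``, ``occlusions``, ``seed``); everything else keeps its
    default.
    """
    if skill not in PRESET_PARAMS:
        raise KineriskError(
            f"unknown skill {skill!r}; available presets: {sorted(PRESET_PARAMS)}"
        )
    if model is None:
        model, _ = default_model()
    params = dict(PRESET_PARAMS[skill])
    script_kw = {"frame_rate": 200.0, "noise_sd_mm": 0.0, "occlusions": [], "seed": 0}
    for key, value in (overrides or {}).items():
        if key in SCRIPT_FIELDS:
            script_kw[key] = value
        elif key in params:
            params[key] = value
        else:
            raise KineriskError(f"unknown preset override {key!r}")
    script_kw["duration"] = script_kw.pop("duration", None) or params["duration"]
    if skill == "pitch":
        params = {**params, "duration": script_kw["duration"]}
        return _pitch_script(params, model, script_kw)
    params = {**params, "duration": script_kw["duration"]}
    return _kick_script(skill, params, model, script_kw)
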
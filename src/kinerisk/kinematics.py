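"""Rigid segment poses from markers; joint angles, ROM, angular velocity.

Per frame, each segment's pose is the least-squares rigid transform (proper
rotation + translation, no scaling) aligning its marker template to the
observed markers — the classic SVD (Kabsch) construction with a reflection
guard. Joint angles are the Cardan decomposition of the relative rotation
``R_rel = R_parent^T R_child``; the default intrinsic ``XYZ`` sequence reads
as flexion/extension about X (lateral axis), abduction/adduction about Y
(anterior axis) and internal/external rotation about Z (longitudinal axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, KineriskError
from .io_formats import MarkerFrameSeries
from .model import SegmentDefinition, SkeletonModel

__all__ = [
    "RigidTransform",
    "SegmentPoseSeries",
    "JointAngleSeries",
    "AngularVelocityResult",
    "fit_segment_pose",
    "fit_pose_series",
    "fit_all_segments",
    "compute_joint_angles",
    "compute_rom",
    "angular_velocity",
]

#: Middle Cardan angle closer than this (degrees) to +-90 raises a per-frame
#: gimbal-proximity flag.
GIMBAL_PROXIMITY_DEG = 1.0


@dataclass
class RigidTransform:
    """Local-to-global rigid transform with its fit residual."""

    rotation: np.ndarray  # (3, 3) proper orthonormal
    translation: np.ndarray  # (3,) mm
    residual_rms: float  # mm

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation


@dataclass
class SegmentPoseSeries:
    """Per-frame rigid poses of one segment."""

    segment: str
    rotations: np.ndarray  # (n, 3, 3)
    translations: np.ndarray  # (n, 3) mm
    residuals: np.ndarray  # (n,) mm RMS
    valid: np.ndarray  # (n,) bool
    frame_rate: float = 200.0

    @property
    def n_frames(self) -> int:
        return self.rotations.shape[0]


@dataclass
class JointAngleSeries:
    """Per-frame Cardan angles (degrees) of one joint, unwrapped over time."""

    joint: str
    angles: np.ndarray  # (n, 3): flexion/extension, abduction/adduction, rotation
    frame_rate: float
    sequence: str = "XYZ"
    gimbal_flags: np.ndarray = field(default=None)  # type: ignore[assignment]
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.gimbal_flags is None:
            self.gimbal_flags = np.zeros(len(self.angles), dtype=bool)
        if self.valid is None:
            self.valid = np.ones(len(self.angles), dtype=bool)

    @property
    def flexion_extension(self) -> np.ndarray:
        return self.angles[:, 0]

    @property
    def abduction_adduction(self) -> np.ndarray:
        return self.angles[:, 1]

    @property
    def rotation(self) -> np.ndarray:
        return self.angles[:, 2]


def fit_segment_pose(
    observed, template: SegmentDefinition | dict
) -> RigidTransform:
    """Least-squares rigid alignment of a marker template to observations.

    Parameters
    ----------
    observed
        Mapping of marker label to observed global 3-vector (mm); markers
        absent from the template are ignored, and vice versa.
    template
        A :class:`SegmentDefinition` or a plain label-to-local-coordinate
        mapping.

    Raises
    ------
    KineriskError
        Fewer than 3 usable shared markers.
    DegenerateGeometryError
        Shared markers are collinear.
    """
    tmpl = template.markers if isinstance(template, SegmentDefinition) else template
    labels = [lb for lb in tmpl if lb in observed]
    if len(labels) < 3:
        raise KineriskError(
            f"pose fit needs >=3 shared markers, got {len(labels)}"
        )
    A = np.array([np.asarray(tmpl[lb], dtype=float) for lb in labels])
    B = np.array([np.asarray(observed[lb], dtype=float) for lb in labels])
    return _kabsch(A, B)


def _kabsch(A: np.ndarray, B: np.ndarray) -> RigidTransform:
    ca = A.mean(axis=0)
    cb = B.mean(axis=0)
    H = (A - ca).T @ (B - cb)
    U, S, Vt = np.linalg.svd(H)
    scale = S[0] if S[0] > 0 else 1.0
    if S[1] / scale < 1e-9:
        raise DegenerateGeometryError("marker configuration is (near-)collinear")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    resid = float(np.sqrt(np.mean(np.sum((A @ R.T + t - B) ** 2, axis=1))))
    return RigidTransform(R, t, resid)


def fit_pose_series(
    series: MarkerFrameSeries, segment: SegmentDefinition
) -> SegmentPoseSeries:
    """Fit one segment's pose in every frame.

    Frames with fewer than 3 usable (non-missing) markers are marked
    invalid rather than raising.
    """
    labels = [lb for lb in segment.markers if lb in series.marker_labels]
    if len(labels) < 3:
        raise KineriskError(
            f"segment {segment.name!r}: only {len(labels)} of its template "
            "markers are present in the series"
        )
    idx = [series.index(lb) for lb in labels]
    tmpl = segment.template_array(labels)
    n = series.n_frames
    rotations = np.tile(np.eye(3), (n, 1, 1))
    translations = np.zeros((n, 3))
    residuals = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    pos = series.positions[idx]  # (k, n, 3)
    miss = series.missing[idx]  # (k, n)
    for f in range(n):
        usable = ~miss[:, f]
        if usable.sum() < 3:
            continue
        try:
            fit = _kabsch(tmpl[usable], pos[usable, f])
        except DegenerateGeometryError:
            continue
        rotations[f] = fit.rotation
        translations[f] = fit.translation
        residuals[f] = fit.residual_rms
        valid[f] = True
    return SegmentPoseSeries(
        segment.name, rotations, translations, residuals, valid, series.frame_rate
    )


def fit_all_segments(
    series: MarkerFrameSeries, model: SkeletonModel
) -> dict[str, SegmentPoseSeries]:
    """Independent per-segment pose fits for every model segment."""
    return {
        name: fit_pose_series(series, model.segments[name])
        for name in model.topological_order
    }


def compute_joint_angles(
    parent: SegmentPoseSeries,
    child: SegmentPoseSeries,
    sequence: str = "XYZ",
    joint_name: str | None = None,
) -> JointAngleSeries:
    """Cardan angles of the child segment relative to its parent.

    The relative rotation ``R_parent^T R_child`` is decomposed in the given
    intrinsic sequence, reported in degrees and unwrapped over time so that
    adjacent frames never jump by more than 180 degrees. Frames within
    ``GIMBAL_PROXIMITY_DEG`` of gimbal lock are flagged but still reported.
    """
    if parent.n_frames != child.n_frames:
        raise KineriskError("parent and child pose series must have equal length")
    n = parent.n_frames
    r_rel = np.einsum("nij,nik->njk", parent.rotations, child.rotations)
    angles = Rotation.from_matrix(r_rel).as_euler(sequence, degrees=True)
    if angles.ndim == 1:
        angles = angles[None, :]
    valid = parent.valid & child.valid
    # unwrap each component over valid frames only
    for c in range(3):
        col = angles[:, c]
        col[valid] = np.unwrap(col[valid], period=360.0)
    gimbal = np.abs(np.abs(angles[:, 1]) - 90.0) < GIMBAL_PROXIMITY_DEG
    return JointAngleSeries(
        joint=joint_name or child.segment,
        angles=angles,
        frame_rate=child.frame_rate,
        sequence=sequence,
        gimbal_flags=gimbal,
        valid=valid,
    )


def compute_rom(angles: np.ndarray) -> float:
    """Range of motion: maximum minus minimum of an angle sequence (degrees)."""
    a = np.asarray(angles, dtype=float)
    a = a[np.isfinite(a)]
    if a.size == 0:
        raise KineriskError("ROM of an empty interval is undefined")
    return float(a.max() - a.min())


@dataclass
class AngularVelocityResult:
    """Central-difference angular velocity with its peak characteristics."""

    omega: np.ndarray  # deg/s per frame
    peak_speed: float  # max |omega|, deg/s
    peak_frame: int
    decel_interval: tuple[int, int]  # maximal contiguous decrease of |omega|
    peak_deceleration: float  # mean d|omega|/dt over that interval, deg/s^2


def angular_velocity(angles: np.ndarray, frame_rate: float) -> AngularVelocityResult:
    """Differentiate an angle series (degrees) into deg/s.

    Central differences interior, one-sided at the edges. Also reports the
    peak speed and the maximal contiguous interval over which |omega|
    decreases (the deceleration burst following a swing peak).
    """
    a = np.asarray(angles, dtype=float)
    if a.size < 3:
        raise KineriskError("angular velocity needs >= 3 frames")
    omega = np.gradient(a, 1.0 / frame_rate)
    speed = np.abs(omega)
    peak_frame = int(np.argmax(speed))
    peak = float(speed[peak_frame])
    # maximal contiguous run of decreasing |omega|
    best = (0, 0)
    best_drop = 0.0
    i = 0
    n = len(speed)
    while i < n - 1:
        if speed[i + 1] < speed[i]:
            j = i
            while j < n - 1 and speed[j + 1] < speed[j]:
                j += 1
            drop = speed[i] - speed[j]
            if drop > best_drop:
                best_drop = drop
                best = (i, j)
            i = j
        else:
            i += 1
    start, end = best
    duration = max(end - start, 1) / frame_rate
    return AngularVelocityResult(
        omega=omega,
        peak_speed=peak,
        peak_frame=peak_frame,
        decel_interval=best,
        peak_deceleration=float(best_drop / duration),
    )
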
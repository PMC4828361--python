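"""Muscle path lengths, rest-length normalization and lengthening speed.

A muscle is a straight-line polyline through its attachment points (origin,
optional via points, insertion), each fixed in a segment-local frame. Per
frame, every point is transformed to global coordinates by its segment's
pose and the length is the sum of consecutive Euclidean distances. Lengths
are normalized to the path's length in a neutral standing posture (the
"rest length") and differentiated into lengthening speed in m/s.

No wrapping surfaces and no force/activation modelling: the path geometry
is the whole model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import KineriskError
from .kinematics import SegmentPoseSeries
from .model import MusclePathDefinition

__all__ = [
    "MuscleLengthSeries",
    "muscle_length",
    "muscle_length_series",
    "compute_rest_length",
    "normalized_lengthening",
    "lengthening_speed",
    "classify_work_pattern",
]

#: |dL/dt| below this (m/s) counts as isometric; avoids chatter from noise
#: at 200 Hz.
DEFAULT_DEAD_BAND_M_S = 0.005


@dataclass
class MuscleLengthSeries:
    """Per-frame path length of one muscle with its rest-length context."""

    muscle: str
    lengths_mm: np.ndarray
    rest_length_mm: float
    frame_rate: float
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.lengths_mm = np.asarray(self.lengths_mm, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.lengths_mm)
        if self.rest_length_mm <= 0:
            raise KineriskError(
                f"muscle {self.muscle!r}: rest length must be > 0"
            )

    @property
    def normalized_pct(self) -> np.ndarray:
        """Length as % of rest length, per frame."""
        return normalized_lengthening(self.lengths_mm, self.rest_length_mm)

    @property
    def speed_m_s(self) -> np.ndarray:
        """Central-difference lengthening speed, m/s (positive = lengthening)."""
        return lengthening_speed(self.lengths_mm, self.frame_rate)[0]

    @property
    def max_normalized_pct(self) -> float:
        vals = self.normalized_pct[self.valid]
        if vals.size == 0:
            raise KineriskError(f"muscle {self.muscle!r}: no valid frames")
        return float(np.nanmax(vals))

    @property
    def peak_lengthening_speed(self) -> float:
        return lengthening_speed(self.lengths_mm, self.frame_rate)[1]


def _transform_point(pose_r: np.ndarray, pose_t: np.ndarray, local: np.ndarray) -> np.ndarray:
    return pose_r @ local + pose_t


def muscle_length(
    path: MusclePathDefinition,
    poses: dict[str, tuple[np.ndarray, np.ndarray]],
) -> float:
    """Polyline length (mm) of a muscle path under one set of segment poses.

    ``poses`` maps segment name to ``(rotation, origin)``. Raises if a
    referenced segment has no pose.
    """
    pts = []
    for seg, local in path.points:
        if seg not in poses:
            raise KineriskError(
                f"muscle {path.name!r}: no pose for segment {seg!r}"
            )
        r, t = poses[seg]
        pts.append(_transform_point(r, t, local))
    pts = np.array(pts)
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def muscle_length_series(
    path: MusclePathDefinition,
    pose_series: dict[str, SegmentPoseSeries],
    rest_length_mm: float,
) -> MuscleLengthSeries:
    """Per-frame muscle lengths from fitted segment pose series.

    Frames where any needed segment's pose is invalid are marked invalid
    for this muscle (length NaN).
    """
    needed = sorted(set(path.segments))
    for seg in needed:
        if seg not in pose_series:
            raise KineriskError(f"muscle {path.name!r}: no pose series for {seg!r}")
    n = pose_series[needed[0]].n_frames
    frame_rate = pose_series[needed[0]].frame_rate
    valid = np.ones(n, dtype=bool)
    for seg in needed:
        valid &= pose_series[seg].valid
    # transform each attachment point across all frames at once
    globals_per_point = []
    for seg, local in path.points:
        ps = pose_series[seg]
        globals_per_point.append(
            np.einsum("nij,j->ni", ps.rotations, local) + ps.translations
        )
    stacked = np.stack(globals_per_point, axis=1)  # (n, n_points, 3)
    lengths = np.sum(
        np.linalg.norm(np.diff(stacked, axis=1), axis=2), axis=1
    )
    lengths = np.where(valid, lengths, np.nan)
    return MuscleLengthSeries(path.name, lengths, rest_length_mm, frame_rate, valid)


def compute_rest_length(
    path: MusclePathDefinition,
    neutral_poses: dict[str, tuple[np.ndarray, np.ndarray]],
) -> float:
    """Muscle length (mm) in the neutral anatomical standing posture."""
    return muscle_length(path, neutral_poses)


def normalized_lengthening(lengths_mm: np.ndarray, rest_length_mm: float) -> np.ndarray:
    """100 * length / rest_length per frame (% of rest length)."""
    if not rest_length_mm > 0:
        raise KineriskError("rest length must be > 0")
    return 100.0 * np.asarray(lengths_mm, dtype=float) / rest_length_mm


def lengthening_speed(
    lengths_mm: np.ndarray, frame_rate: float
) -> tuple[np.ndarray, float]:
    """Central-difference dL/dt in m/s, plus the maximum over lengthening
    (positive-speed) intervals.

    Needs at least 3 valid frames.
    """
    x = np.asarray(lengths_mm, dtype=float)
    if np.sum(np.isfinite(x)) < 3:
        raise KineriskError("lengthening speed needs >= 3 valid frames")
    speed = np.gradient(x, 1.0 / frame_rate) / 1000.0  # mm/s -> m/s
    positive = speed[np.isfinite(speed) & (speed > 0)]
    max_pos = float(positive.max()) if positive.size else 0.0
    return speed, max_pos


def classify_work_pattern(
    lengths_mm: np.ndarray,
    frame_rate: float,
    dead_band_m_s: float = DEFAULT_DEAD_BAND_M_S,
) -> np.ndarray:
    """Label every frame lengthening / shortening / isometric.

    Kinematic proxies: a lengthening muscle under load works eccentrically,
    a shortening one concentrically; without activation data the labels stay
    kinematic.
    """
    speed, _ = lengthening_speed(lengths_mm, frame_rate)
    labels = np.full(len(speed), "isometric", dtype=object)
    labels[speed > dead_band_m_s] = "lengthening"
    labels[speed < -dead_band_m_s] = "shortening"
    return labels
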
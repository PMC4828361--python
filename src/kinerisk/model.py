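"""Skeleton and muscle-path configuration.

A :class:`SkeletonModel` is the geometric scaffold of the analysis: named
rigid segments arranged in a joint tree (single root at the pelvis), each
with >=3 non-collinear template markers in segment-local coordinates and a
per-joint Cardan (Euler) sequence. Muscles are polyline paths of >=2
attachment points expressed in segment-local coordinates.

Segment-local frames are aligned with the global frame in the neutral
(anatomical standing) posture, with each segment's origin at its proximal
joint centre. Convention: right-handed, X lateral (subject's right), Y
anterior, Z up, millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import ModelValidationError

__all__ = [
    "SegmentDefinition",
    "SkeletonModel",
    "MusclePathDefinition",
    "load_model_config",
    "default_model",
    "default_model_path",
]

#: Default Cardan sequence: flexion/extension about X, abduction/adduction
#: about Y, internal/external rotation about Z (intrinsic).
DEFAULT_EULER_SEQUENCE = "XYZ"


@dataclass
class SegmentDefinition:
    """One rigid body segment.

    ``markers`` maps marker labels to template coordinates in the
    segment-local frame (mm). ``origin_in_parent`` is the proximal joint
    centre expressed in the parent's local frame (or globally for the root).
    """

    name: str
    parent: str | None
    origin_in_parent: np.ndarray
    markers: dict[str, np.ndarray]
    euler_sequence: str = DEFAULT_EULER_SEQUENCE
    joint_name: str | None = None

    def __post_init__(self) -> None:
        self.origin_in_parent = np.asarray(self.origin_in_parent, dtype=float)
        self.markers = {k: np.asarray(v, dtype=float) for k, v in self.markers.items()}
        if len(self.markers) < 3:
            raise ModelValidationError(
                f"segment {self.name!r} has {len(self.markers)} template markers; >=3 required"
            )
        if self.origin_in_parent.shape != (3,):
            raise ModelValidationError(f"segment {self.name!r}: origin must be a 3-vector")
        pts = np.array(list(self.markers.values()))
        if _collinear(pts):
            raise ModelValidationError(
                f"segment {self.name!r}: template markers are collinear"
            )
        if self.joint_name is None and self.parent is not None:
            self.joint_name = f"{self.name}"

    @property
    def marker_labels(self) -> list[str]:
        return list(self.markers)

    def template_array(self, labels: list[str] | None = None) -> np.ndarray:
        labels = labels if labels is not None else self.marker_labels
        return np.array([self.markers[lb] for lb in labels])


def _collinear(points: np.ndarray, tol: float = 1e-6) -> bool:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    scale = s[0] if s[0] > 0 else 1.0
    return bool(s[1] / scale < tol)


@dataclass
class MusclePathDefinition:
    """Ordered polyline muscle path: origin, optional via points, insertion."""

    name: str
    points: list[tuple[str, np.ndarray]]

    def __post_init__(self) -> None:
        self.points = [(seg, np.asarray(p, dtype=float)) for seg, p in self.points]
        if len(self.points) < 2:
            raise ModelValidationError(
                f"muscle {self.name!r} needs >=2 attachment points"
            )

    @property
    def segments(self) -> list[str]:
        return [seg for seg, _ in self.points]


class SkeletonModel:
    """Rigid-segment tree with marker templates.

    Parameters
    ----------
    segments
        Segment definitions; exactly one must have ``parent=None`` (the root,
        conventionally the pelvis / lower trunk).
    """

    def __init__(self, segments: list[SegmentDefinition]):
        self.segments: dict[str, SegmentDefinition] = {}
        for seg in segments:
            if seg.name in self.segments:
                raise ModelValidationError(f"duplicate segment name {seg.name!r}")
            self.segments[seg.name] = seg
        roots = [s.name for s in segments if s.parent is None]
        if len(roots) != 1:
            raise ModelValidationError(
                f"joint tree must have exactly one root, found {roots}"
            )
        self.root = roots[0]
        for seg in segments:
            if seg.parent is not None and seg.parent not in self.segments:
                raise ModelValidationError(
                    f"segment {seg.name!r} references unknown parent {seg.parent!r}"
                )
        self.topological_order = self._toposort()

    def _toposort(self) -> list[str]:
        children: dict[str, list[str]] = {name: [] for name in self.segments}
        for seg in self.segments.values():
            if seg.parent is not None:
                children[seg.parent].append(seg.name)
        order: list[str] = []
        stack = [self.root]
        while stack:
            name = stack.pop()
            order.append(name)
            stack.extend(reversed(children[name]))
        if len(order) != len(self.segments):
            unreached = set(self.segments) - set(order)
            raise ModelValidationError(
                f"joint tree is cyclic or disconnected; unreachable: {sorted(unreached)}"
            )
        return order

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def marker_labels(self) -> list[str]:
        """All distinct marker labels, in topological segment order."""
        seen: dict[str, None] = {}
        for name in self.topological_order:
            for lb in self.segments[name].markers:
                seen.setdefault(lb, None)
        return list(seen)

    def marker_owner(self) -> dict[str, str]:
        """Owner segment per marker (first in topological order listing it).

        Shared markers sit at joint centres / axes, so generation from the
        owner segment is consistent with every other segment listing them.
        """
        owner: dict[str, str] = {}
        for name in self.topological_order:
            for lb in self.segments[name].markers:
                owner.setdefault(lb, name)
        return owner

    def joints(self) -> list[tuple[str, str, str]]:
        """(joint_name, parent_segment, child_segment) per non-root segment."""
        out = []
        for name in self.topological_order:
            seg = self.segments[name]
            if seg.parent is not None:
                out.append((seg.joint_name or name, seg.parent, name))
        return out

    def neutral_poses(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Identity-orientation poses of the neutral posture.

        Returns per-segment ``(rotation, origin)`` with rotation = I and the
        origin composed down the tree from ``origin_in_parent`` offsets.
        """
        poses: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for name in self.topological_order:
            seg = self.segments[name]
            if seg.parent is None:
                origin = seg.origin_in_parent.copy()
            else:
                origin = poses[seg.parent][1] + seg.origin_in_parent
            poses[name] = (np.eye(3), origin)
        return poses


def _validate_muscles(model: SkeletonModel, muscles: list[MusclePathDefinition]) -> None:
    for muscle in muscles:
        for seg, _ in muscle.points:
            if seg not in model.segments:
                raise ModelValidationError(
                    f"muscle {muscle.name!r} references unknown segment {seg!r}"
                )


def load_model_config(
    path: str | Path, *, full_body: bool = True
) -> tuple[SkeletonModel, list[MusclePathDefinition]]:
    """Load a skeleton + muscle configuration from a YAML/JSON tree.

    With ``full_body=True`` (the default, matching the analysis model) the
    config must define exactly 15 segments; pass ``False`` for reduced test
    rigs.
    """
    path = Path(path)
    config = yaml.safe_load(path.read_text())
    if not isinstance(config, dict) or "segments" not in config:
        raise ModelValidationError(f"{path}: config must contain a 'segments' mapping")
    convention = config.get("coordinate_convention", {})
    if convention:
        if convention.get("up_axis", "z") != "z" or convention.get("units", "mm") != "mm":
            raise ModelValidationError(
                f"{path}: unsupported coordinate convention {convention!r} "
                "(expected z-up, mm)"
            )
    segments = []
    for name, entry in config["segments"].items():
        segments.append(
            SegmentDefinition(
                name=name,
                parent=entry.get("parent"),
                origin_in_parent=entry.get("origin_in_parent", [0.0, 0.0, 0.0]),
                markers=entry.get("markers", {}),
                euler_sequence=entry.get("euler_sequence", DEFAULT_EULER_SEQUENCE),
                joint_name=entry.get("joint"),
            )
        )
    model = SkeletonModel(segments)
    if full_body and model.n_segments != 15:
        raise ModelValidationError(
            f"{path}: full-body model requires 15 segments, found {model.n_segments}"
        )
    muscles = []
    for name, entry in config.get("muscles", {}).items():
        points = [(p["segment"], p["position"]) for p in entry["points"]]
        muscles.append(MusclePathDefinition(name=name, points=points))
    _validate_muscles(model, muscles)
    return model, muscles


def default_model_path() -> Path:
    """Path of the bundled default full-body configuration."""
    return Path(str(resources.files("kinerisk") / "data" / "default_model.yaml"))


def default_model() -> tuple[SkeletonModel, list[MusclePathDefinition]]:
    """The bundled 15-segment, 42-marker model with the nine studied muscles.

    Attachment coordinates are plausible fixtures expressed in segment-local
    mm, not anatomical ground truth.
    """
    return load_model_config(default_model_path())
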
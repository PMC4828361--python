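"""Injury-risk criteria: the >120%-of-rest-length threshold, impact-like
eccentric loading detection, and pitching phase segmentation.

Animal lesion studies place the repetitive-stress-injury danger zone at
muscle excursions beyond 120% of rest length; a muscle is flagged "at risk"
when its maximum normalized lengthening strictly exceeds that threshold.
Impact-like eccentric loading — an abrupt, sub-100 ms surge of lengthening
speed while the muscle lengthens, typical of arm deceleration after ball
release — is detected with a configurable rise-window / rise-factor rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import KineriskError, SegmentationError
from .kinematics import JointAngleSeries
from .muscle_model import MuscleLengthSeries

__all__ = [
    "RiskAssessment",
    "ImpactLikeEvent",
    "PitchPhaseSegmentation",
    "assess_risk",
    "assess_risk_value",
    "rank_muscles",
    "detect_impact_like",
    "segment_pitch_phases",
    "DEFAULT_RISK_THRESHOLD_PCT",
]

#: Critical normalized lengthening (% of rest length); flagged strictly above.
DEFAULT_RISK_THRESHOLD_PCT = 120.0

PITCH_EVENT_NAMES = (
    "initial_position",
    "balance_point",
    "foot_contact",
    "max_shoulder_external_rotation",
    "ball_release",
    "max_shoulder_internal_rotation",
    "fielding_position",
)

PITCH_PHASE_NAMES = (
    "wind_up",
    "stride",
    "arm_cocking",
    "arm_acceleration",
    "arm_deceleration",
    "follow_through",
)


@dataclass(frozen=True)
class ImpactLikeEvent:
    """An abrupt rise of lengthening speed while the muscle lengthens."""

    start_frame: int
    end_frame: int
    speed_rise_m_s2: float  # mean rate of speed increase over the interval


@dataclass
class RiskAssessment:
    """Per-muscle verdict of the over-lengthening criterion."""

    muscle: str
    max_normalized_pct: float
    threshold_pct: float = DEFAULT_RISK_THRESHOLD_PCT
    peak_lengthening_speed_m_s: float = float("nan")
    impact_like_events: list[ImpactLikeEvent] = field(default_factory=list)

    @property
    def at_risk(self) -> bool:
        """Strictly greater-than: exactly 120.0% is not flagged."""
        return self.max_normalized_pct > self.threshold_pct


def assess_risk_value(
    muscle: str,
    max_normalized_pct: float,
    threshold_pct: float = DEFAULT_RISK_THRESHOLD_PCT,
) -> RiskAssessment:
    """Apply the over-lengthening criterion to a single reported value.

    Useful for published per-muscle group means, where no frame-level
    series exists.
    """
    if not threshold_pct > 0:
        raise KineriskError("risk threshold must be > 0")
    return RiskAssessment(muscle, float(max_normalized_pct), threshold_pct)


def assess_risk(
    series: MuscleLengthSeries,
    threshold_pct: float = DEFAULT_RISK_THRESHOLD_PCT,
    rise_window_ms: float = 100.0,
    rise_factor: float = 3.0,
) -> RiskAssessment:
    """Full per-muscle assessment from a frame-level length series."""
    if not threshold_pct > 0:
        raise KineriskError("risk threshold must be > 0")
    if not series.valid.any():
        raise KineriskError(f"muscle {series.muscle!r}: no valid frames")
    speed = series.speed_m_s
    events = detect_impact_like(
        speed, series.frame_rate, rise_window_ms=rise_window_ms, rise_factor=rise_factor
    )
    return RiskAssessment(
        muscle=series.muscle,
        max_normalized_pct=series.max_normalized_pct,
        threshold_pct=threshold_pct,
        peak_lengthening_speed_m_s=series.peak_lengthening_speed,
        impact_like_events=events,
    )


def rank_muscles(
    assessments: list[RiskAssessment],
) -> tuple[list[RiskAssessment], list[RiskAssessment]]:
    """Order descending by max normalized lengthening; return (all, flagged)."""
    if not assessments:
        raise KineriskError("rank_muscles needs >= 1 assessment")
    ordered = sorted(
        assessments, key=lambda a: a.max_normalized_pct, reverse=True
    )
    flagged = [a for a in ordered if a.at_risk]
    return ordered, flagged


def detect_impact_like(
    speed_m_s: np.ndarray,
    frame_rate: float,
    rise_window_ms: float = 100.0,
    rise_factor: float = 3.0,
) -> list[ImpactLikeEvent]:
    """Detect abrupt rises of lengthening speed during lengthening.

    An event is an interval over which the speed climbs from below the
    series median to at least ``rise_factor`` times the median within at
    most ``rise_window_ms``, with the muscle lengthening (speed > 0)
    throughout the climb. The window/factor rule encodes the two cues of
    the phenomenon — a "speedy increase" over less than ~100 ms — and both
    are configurable.
    """
    speed = np.asarray(speed_m_s, dtype=float)
    n = speed.size
    window = int(round(rise_window_ms * frame_rate / 1000.0))
    if n < max(window, 3):
        raise KineriskError("speed series shorter than the rise window")
    finite = speed[np.isfinite(speed)]
    if finite.size == 0:
        return []
    median = float(np.median(finite))
    if median <= 0:
        return []  # degenerate (e.g. all-zero) baseline: nothing to rise from
    high = rise_factor * median
    events: list[ImpactLikeEvent] = []
    f = 0
    while f < n:
        if np.isfinite(speed[f]) and speed[f] >= high and speed[f] > 0:
            # walk back to the most recent at-or-below-median frame
            start = f
            while start > 0 and np.isfinite(speed[start - 1]) and speed[start - 1] > median:
                start -= 1
            start = max(start - 1, 0)
            rise_frames = f - start
            climb = speed[start:f + 1]
            lengthening = np.all(climb[np.isfinite(climb)][1:] > 0)
            if rise_frames <= window and speed[start] <= median and lengthening:
                end = f  # extend over the rest of the climb
                while end < n - 1 and np.isfinite(speed[end + 1]) and speed[end + 1] > speed[end]:
                    end += 1
                dt = max(rise_frames, 1) / frame_rate
                events.append(
                    ImpactLikeEvent(start, end, float((speed[f] - speed[start]) / dt))
                )
                f = end
                # skip the rest of this excursion above the median
                while f < n and np.isfinite(speed[f]) and speed[f] >= median:
                    f += 1
                continue
        f += 1
    return events


@dataclass
class PitchPhaseSegmentation:
    """Seven critical event frames and the six phases they bound."""

    events: dict[str, int]  # name -> frame (PITCH_EVENT_NAMES order)
    frame_rate: float

    def __post_init__(self) -> None:
        frames = [self.events[name] for name in PITCH_EVENT_NAMES]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise SegmentationError(
                f"event frames must be strictly increasing, got {self.events}"
            )

    @property
    def phases(self) -> dict[str, tuple[int, int]]:
        frames = [self.events[name] for name in PITCH_EVENT_NAMES]
        return {
            name: (frames[i], frames[i + 1])
            for i, name in enumerate(PITCH_PHASE_NAMES)
        }


def segment_pitch_phases(
    shoulder_angles: JointAngleSeries,
    hand_speed_m_s: np.ndarray,
    lead_foot_height_mm: np.ndarray,
    contact_tolerance: float = 0.002,
) -> PitchPhaseSegmentation:
    """Locate the seven pitching events from kinematic series.

    Detection rules: balance point = peak lead-foot height; foot contact =
    onset of the post-balance height minimum (first frame within
    ``contact_tolerance`` of the minimum, as a fraction of the height
    range); maximum external/internal shoulder rotation = extrema of the
    axial rotation angle after foot contact; ball release = peak hand speed
    between the two rotation extrema; initial/fielding = trial bounds.

    Raises :class:`SegmentationError` when the rotation angle has no
    interior extremum (degenerate, e.g. monotone input) or the detected
    events are not strictly increasing.
    """
    rot = np.asarray(shoulder_angles.rotation, dtype=float)
    hand = np.asarray(hand_speed_m_s, dtype=float)
    foot = np.asarray(lead_foot_height_mm, dtype=float)
    n = len(rot)
    if not (len(hand) == len(foot) == n):
        raise SegmentationError("input series must be aligned (equal length)")
    if n < 7:
        raise SegmentationError("trial too short to segment")

    initial = 0
    fielding = n - 1
    balance = int(np.argmax(foot))
    after = foot[balance + 1 :]
    if after.size == 0:
        raise SegmentationError("lead-foot height peaks at the trial end")
    height_range = float(foot.max() - after.min())
    tol = contact_tolerance * height_range if height_range > 0 else 0.0
    rel = np.nonzero(after <= after.min() + tol)[0]
    foot_contact = balance + 1 + int(rel[0])

    seg = rot[foot_contact:]
    mer = foot_contact + int(np.argmax(seg))
    if mer in (foot_contact, n - 1):
        raise SegmentationError(
            "no interior maximum of shoulder external rotation (monotone angle?)"
        )
    mir = mer + int(np.argmin(rot[mer:]))
    if mir in (mer, n - 1):
        raise SegmentationError(
            "no interior maximum of shoulder internal rotation (monotone angle?)"
        )
    release = mer + 1 + int(np.argmax(hand[mer + 1 : mir]))

    events = dict(
        zip(
            PITCH_EVENT_NAMES,
            (initial, balance, foot_contact, mer, release, mir, fielding),
        )
    )
    try:
        return PitchPhaseSegmentation(events, shoulder_angles.frame_rate)
    except SegmentationError as exc:
        raise SegmentationError(f"detected events are inconsistent: {exc}") from None
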
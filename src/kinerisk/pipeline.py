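"""End-to-end analysis: markers in, ROM / muscle-risk report out.

The stages mirror the capture-to-report workflow: read trajectories, fill
occlusion gaps, apply the five-point smoothing filter to raw coordinates,
fit per-segment rigid poses, derive joint angles and ROM, track muscle path
lengths against their neutral-posture rest lengths, and apply the
over-lengthening risk criterion. A pitch trial additionally gets its seven
critical events and six phases segmented. Group comparisons run
independent t-tests per variable, from raw per-trial values when available
or from summary statistics otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import KineriskError
from .io_formats import (
    MarkerFrameSeries,
    read_c3d,
    read_csv,
    read_trc,
    write_report_json,
)
from .kinematics import (
    JointAngleSeries,
    compute_joint_angles,
    compute_rom,
    fit_all_segments,
)
from .model import (
    MusclePathDefinition,
    SkeletonModel,
    default_model,
    load_model_config,
)
from .muscle_model import (
    MuscleLengthSeries,
    compute_rest_length,
    muscle_length_series,
)
from .preprocess import Gap, fill_gaps, smooth_series
from .risk_analysis import (
    DEFAULT_RISK_THRESHOLD_PCT,
    PitchPhaseSegmentation,
    RiskAssessment,
    assess_risk,
    segment_pitch_phases,
)
from .stats import DEFAULT_ALPHA, GroupSummary, TTestResult, t_test_from_summary, t_test_raw

logger = logging.getLogger("kinerisk")

__all__ = ["RunConfig", "AnalysisResult", "run_analysis", "run_comparison", "aggregate_trials"]


@dataclass
class RunConfig:
    """Configuration of one analysis run."""

    input_path: str | Path | None = None
    series: MarkerFrameSeries | None = None  # in-memory alternative to input_path
    model_path: str | Path | None = None  # None -> bundled default model
    smoothing: bool = True
    gap_fill_limit: int = 10  # frames (50 ms at 200 Hz)
    risk_threshold_pct: float = DEFAULT_RISK_THRESHOLD_PCT
    alpha: float = DEFAULT_ALPHA
    skill: str | None = None  # "pitch" enables phase segmentation
    throwing_side: str = "r"
    lead_side: str = "l"
    output_dir: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.risk_threshold_pct > 0:
            raise KineriskError("risk threshold must be > 0")
        if not 0 < self.alpha < 1:
            raise KineriskError("alpha must lie in (0, 1)")


@dataclass
class AnalysisResult:
    """Everything one trial's analysis produced."""

    rom_table: pd.DataFrame  # joint, component, rom_deg
    muscle_table: pd.DataFrame  # muscle, max %, speed, at_risk, events
    assessments: list[RiskAssessment]
    angle_series: dict[str, JointAngleSeries]
    muscle_series: dict[str, MuscleLengthSeries]
    gap_report: list[Gap]
    segmentation: PitchPhaseSegmentation | None = None


def _read_input(path: str | Path) -> MarkerFrameSeries:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".trc":
        return read_trc(path)
    if suffix == ".csv":
        return read_csv(path)
    if suffix == ".c3d":
        return read_c3d(path)
    raise KineriskError(f"unsupported input format {suffix!r} (expect .trc/.csv/.c3d)")


def _load_model(
    config: RunConfig,
) -> tuple[SkeletonModel, list[MusclePathDefinition]]:
    if config.model_path is None:
        return default_model()
    return load_model_config(config.model_path)


def run_analysis(config: RunConfig) -> AnalysisResult:
    """Run the full single-trial analysis.

    Deterministic given inputs and config. Output files (when
    ``output_dir`` is set) are written only after every stage succeeded, so
    a failing stage leaves no partial report behind.
    """
    if (config.series is None) == (config.input_path is None):
        raise KineriskError("provide exactly one of input_path or series")
    series = config.series if config.series is not None else _read_input(config.input_path)
    model, muscles = _load_model(config)
    logger.info("input: %d markers x %d frames at %g Hz",
                series.n_markers, series.n_frames, series.frame_rate)

    series, gap_report = fill_gaps(series, config.gap_fill_limit)
    unfilled = [g for g in gap_report if not g.filled]
    if gap_report:
        logger.info("gap fill: %d gaps, %d left unfilled", len(gap_report), len(unfilled))
    if config.smoothing:
        series = smooth_series(series)
        logger.info("applied five-point (1-3-4-3-1) smoothing")

    poses = fit_all_segments(series, model)
    for name, ps in poses.items():
        logger.debug("segment %s: %d/%d valid frames, residual RMS %.3f mm",
                     name, int(ps.valid.sum()), ps.n_frames,
                     float(np.nanmean(ps.residuals)))

    angle_series: dict[str, JointAngleSeries] = {}
    rom_rows = []
    for joint, parent, child in model.joints():
        ja = compute_joint_angles(
            poses[parent], poses[child],
            sequence=model.segments[child].euler_sequence, joint_name=joint,
        )
        angle_series[joint] = ja
        for c, comp in enumerate(
            ("flexion_extension", "abduction_adduction", "rotation")
        ):
            rom_rows.append(
                {
                    "joint": joint,
                    "component": comp,
                    "rom_deg": compute_rom(ja.angles[ja.valid, c]),
                }
            )
        logger.debug("joint %s: %d frames", joint, ja.angles.shape[0])
    rom_table = pd.DataFrame(rom_rows)

    neutral = model.neutral_poses()
    muscle_series: dict[str, MuscleLengthSeries] = {}
    assessments: list[RiskAssessment] = []
    muscle_rows = []
    for muscle in muscles:
        rest = compute_rest_length(muscle, neutral)
        ms = muscle_length_series(muscle, poses, rest)
        muscle_series[muscle.name] = ms
        assessment = assess_risk(ms, threshold_pct=config.risk_threshold_pct)
        assessments.append(assessment)
        muscle_rows.append(
            {
                "muscle": muscle.name,
                "rest_length_mm": rest,
                "max_normalized_pct": assessment.max_normalized_pct,
                "peak_lengthening_speed_m_s": assessment.peak_lengthening_speed_m_s,
                "at_risk": assessment.at_risk,
                "n_impact_like_events": len(assessment.impact_like_events),
            }
        )
        logger.info("muscle %s: max %.1f%% of rest, at_risk=%s",
                    muscle.name, assessment.max_normalized_pct, assessment.at_risk)
    muscle_table = (
        pd.DataFrame(muscle_rows)
        .sort_values("max_normalized_pct", ascending=False)
        .reset_index(drop=True)
    )

    segmentation = None
    if config.skill == "pitch":
        shoulder = angle_series[f"shoulder_{config.throwing_side}"]
        hand = poses[f"hand_{config.throwing_side}"]
        dt = 1.0 / series.frame_rate
        hand_speed = (
            np.linalg.norm(np.gradient(hand.translations, dt, axis=0), axis=1) / 1000.0
        )
        foot_height = poses[f"foot_{config.lead_side}"].translations[:, 2]
        segmentation = segment_pitch_phases(shoulder, hand_speed, foot_height)
        logger.info("pitch events: %s", segmentation.events)

    result = AnalysisResult(
        rom_table=rom_table,
        muscle_table=muscle_table,
        assessments=assessments,
        angle_series=angle_series,
        muscle_series=muscle_series,
        gap_report=gap_report,
        segmentation=segmentation,
    )
    if config.output_dir is not None:
        _write_outputs(result, Path(config.output_dir))
    return result


def _write_outputs(result: AnalysisResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.rom_table.to_csv(out_dir / "rom.csv", index=False)
    result.muscle_table.to_csv(out_dir / "muscles.csv", index=False)
    report = {
        "rom": result.rom_table.to_dict(orient="records"),
        "muscles": result.muscle_table.to_dict(orient="records"),
        "gaps": [vars(g) for g in result.gap_report],
    }
    if result.segmentation is not None:
        report["pitch_events"] = result.segmentation.events
        report["pitch_phases"] = {
            k: list(v) for k, v in result.segmentation.phases.items()
        }
        events = pd.DataFrame(
            [
                {"event": name, "frame": frame,
                 "time_s": frame / result.segmentation.frame_rate}
                for name, frame in result.segmentation.events.items()
            ]
        )
        events.to_csv(out_dir / "pitch_events.csv", index=False)
    write_report_json(report, out_dir / "report.json")


def run_comparison(
    group_a: dict,
    group_b: dict,
    variant: str = "pooled",
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-variable independent t-tests between two groups.

    Each group maps variable names to either a :class:`GroupSummary` or raw
    per-trial values; raw values use :func:`t_test_raw`, summaries use
    :func:`t_test_from_summary`. Variable sets must match.
    """
    mismatched = set(group_a) ^ set(group_b)
    if mismatched:
        raise KineriskError(
            f"variable sets differ between groups: {sorted(mismatched)}"
        )
    rows = []
    for var in group_a:
        a, b = group_a[var], group_b[var]
        sa = a if isinstance(a, GroupSummary) else None
        sb = b if isinstance(b, GroupSummary) else None
        if sa is not None and sb is not None:
            res: TTestResult = t_test_from_summary(sa, sb, variant=variant, alpha=alpha)
        elif sa is None and sb is None:
            res = t_test_raw(a, b, variant=variant, alpha=alpha)
            sa, sb = (
                GroupSummary(float(np.mean(a)), float(np.std(a, ddof=1)), len(a)),
                GroupSummary(float(np.mean(b)), float(np.std(b, ddof=1)), len(b)),
            )
        else:
            raise KineriskError(
                f"variable {var!r}: both groups must be raw or both summaries"
            )
        rows.append(
            {
                "variable": var,
                "mean_a": sa.mean, "sd_a": sa.sd, "n_a": sa.n,
                "mean_b": sb.mean, "sd_b": sb.sd, "n_b": sb.n,
                "t": res.t, "df": res.df, "p": res.p,
                "significant": res.significant,
            }
        )
    return pd.DataFrame(rows)


def aggregate_trials(muscle_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Merge per-trial muscle tables into mean +- SD group rows.

    Per-subject values are conventionally the mean over that subject's
    trials; pass one table per subject (already trial-averaged) or per
    trial, as your design dictates.
    """
    if not muscle_tables:
        raise KineriskError("no tables to aggregate")
    stacked = pd.concat(muscle_tables, ignore_index=True)
    agg = (
        stacked.groupby("muscle")
        .agg(
            max_normalized_pct_mean=("max_normalized_pct", "mean"),
            max_normalized_pct_sd=("max_normalized_pct", "std"),
            peak_speed_mean=("peak_lengthening_speed_m_s", "mean"),
            peak_speed_sd=("peak_lengthening_speed_m_s", "std"),
            n=("max_normalized_pct", "size"),
        )
        .reset_index()
        .sort_values("max_normalized_pct_mean", ascending=False)
        .reset_index(drop=True)
    )
    return agg
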
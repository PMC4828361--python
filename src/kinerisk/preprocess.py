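"""Gap handling and five-point (1-3-4-3-1) trajectory smoothing.

Raw marker coordinates are smoothed with the symmetric five-point kernel
(1, 3, 4, 3, 1)/12 before any pose fitting; derived angle and length series
are not re-smoothed. At the two samples nearest each edge the kernel is
truncated and renormalized, which preserves series length without
extrapolating phantom samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MissingDataError
from .io_formats import MarkerFrameSeries

__all__ = [
    "FIVE_POINT_WEIGHTS",
    "Gap",
    "fill_gaps",
    "smooth_five_point",
    "smooth_series",
]

#: The five-point smoothing kernel, normalized by its sum (12).
FIVE_POINT_WEIGHTS = np.array([1.0, 3.0, 4.0, 3.0, 1.0]) / 12.0


@dataclass(frozen=True)
class Gap:
    """A run of missing samples for one marker."""

    marker: str
    start: int  # first missing frame
    length: int
    filled: bool


def _runs_of_missing(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) for each maximal run of True in ``mask``."""
    runs = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def fill_gaps(
    series: MarkerFrameSeries, max_gap: int
) -> tuple[MarkerFrameSeries, list[Gap]]:
    """Linearly interpolate short occlusion gaps per coordinate.

    Interior gaps of at most ``max_gap`` frames are filled by linear
    interpolation between the bounding samples; longer gaps are left missing
    and reported. Edge gaps are held at the nearest valid value regardless
    of length (there is nothing to interpolate towards).

    Returns the repaired series and a gap report.

    Raises
    ------
    MissingDataError
        If a marker is missing in every frame.
    """
    out = series.copy()
    report: list[Gap] = []
    for m, label in enumerate(series.marker_labels):
        mask = series.missing[m]
        if mask.all():
            raise MissingDataError(f"marker {label!r} is missing in all frames")
        for start, length in _runs_of_missing(mask):
            end = start + length  # first valid frame after the gap
            at_left_edge = start == 0
            at_right_edge = end == series.n_frames
            if at_left_edge:
                out.positions[m, :end] = series.positions[m, end]
                out.missing[m, :end] = False
                report.append(Gap(label, start, length, True))
            elif at_right_edge:
                out.positions[m, start:] = series.positions[m, start - 1]
                out.missing[m, start:] = False
                report.append(Gap(label, start, length, True))
            elif length <= max_gap:
                left = series.positions[m, start - 1]
                right = series.positions[m, end]
                t = np.arange(1, length + 1)[:, None] / (length + 1)
                out.positions[m, start:end] = left + t * (right - left)
                out.missing[m, start:end] = False
                report.append(Gap(label, start, length, True))
            else:
                report.append(Gap(label, start, length, False))
    return out, report


def smooth_five_point(signal: np.ndarray) -> np.ndarray:
    """Apply the (1,3,4,3,1)/12 smoothing kernel to a scalar sequence.

    Interior samples become the symmetric weighted mean of their five-point
    neighbourhood; the two samples nearest each edge use the truncated,
    renormalized kernel. Output length equals input length.

    Raises
    ------
    MissingDataError
        If the sequence contains NaN (fill gaps first).
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("smooth_five_point expects a 1-D sequence")
    if x.size < 1:
        raise ValueError("sequence must have length >= 1")
    if np.isnan(x).any():
        raise MissingDataError("sequence contains missing values; run fill_gaps first")
    n = x.size
    if n == 1:
        return x.copy()
    w = FIVE_POINT_WEIGHTS
    out = np.empty_like(x)
    for i in range(n):
        lo = max(0, i - 2)
        hi = min(n, i + 3)
        ww = w[lo - i + 2 : hi - i + 2]
        out[i] = np.dot(ww, x[lo:hi]) / ww.sum()
    return out


def smooth_series(series: MarkerFrameSeries) -> MarkerFrameSeries:
    """Smooth every marker coordinate channel of a series.

    Each maximal run of non-missing samples is smoothed independently, so
    unfilled long gaps neither propagate NaN nor couple disjoint runs.
    """
    out = series.copy()
    for m in range(series.n_markers):
        valid = ~series.missing[m]
        i = 0
        n = series.n_frames
        while i < n:
            if valid[i]:
                j = i
                while j < n and valid[j]:
                    j += 1
                for axis in range(3):
                    out.positions[m, i:j, axis] = smooth_five_point(
                        series.positions[m, i:j, axis]
                    )
                i = j
            else:
                i += 1
    return out
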
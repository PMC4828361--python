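"""Reading and writing marker-trajectory files (TRC, CSV, optionally C3D).

The in-memory container is :class:`MarkerFrameSeries`: labeled 3D marker
positions in millimetres over time at a fixed frame rate, with an explicit
per-sample missing flag (zeros are valid coordinates and never mean
"missing").

Coordinate convention throughout the package: right-handed, Z vertical (up),
units mm, 0-based frame indexing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError

__all__ = [
    "MarkerFrameSeries",
    "read_trc",
    "write_trc",
    "read_csv",
    "write_csv",
    "read_c3d",
    "write_c3d",
    "write_report_json",
]


@dataclass
class MarkerFrameSeries:
    """Labeled 3D marker positions over time.

    Parameters
    ----------
    marker_labels
        Ordered marker names; one entry per marker.
    frame_rate
        Sampling rate in Hz (> 0).
    positions
        Array of shape ``(n_markers, n_frames, 3)`` in millimetres.
    missing
        Boolean array of shape ``(n_markers, n_frames)``; True marks an
        invalid/occluded sample. Missing positions may hold NaN.
    """

    marker_labels: list[str]
    frame_rate: float
    positions: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_markers, n_frames, 3)")
        if self.missing is None:
            self.missing = np.zeros(self.positions.shape[:2], dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != self.positions.shape[:2]:
            raise ValueError("missing must have shape (n_markers, n_frames)")
        if len(self.marker_labels) != self.positions.shape[0]:
            raise ValueError("one label per marker required")
        if len(set(self.marker_labels)) != len(self.marker_labels):
            raise ValueError("marker labels must be unique")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not np.all(np.isfinite(self.positions[~self.missing])):
            raise ValueError("non-missing positions must be finite")

    @property
    def n_markers(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_frames) / self.frame_rate

    def index(self, label: str) -> int:
        try:
            return self.marker_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown marker label {label!r}") from None

    def marker(self, label: str) -> np.ndarray:
        """Positions of one marker, shape ``(n_frames, 3)``."""
        return self.positions[self.index(label)]

    def copy(self) -> "MarkerFrameSeries":
        return MarkerFrameSeries(
            list(self.marker_labels),
            self.frame_rate,
            self.positions.copy(),
            self.missing.copy(),
        )

    def allclose(self, other: "MarkerFrameSeries", atol: float = 0.01) -> bool:
        """Equality up to numeric text precision (default 0.01 mm)."""
        if self.marker_labels != other.marker_labels:
            return False
        if abs(self.frame_rate - other.frame_rate) > 1e-9:
            return False
        if self.positions.shape != other.positions.shape:
            return False
        if not np.array_equal(self.missing, other.missing):
            return False
        ok = ~self.missing
        return bool(np.allclose(self.positions[ok], other.positions[ok], atol=atol))


# ---------------------------------------------------------------------------
# TRC (tab-separated, the standard mocap text dialect)
# ---------------------------------------------------------------------------

_UNIT_TO_MM = {"mm": 1.0, "cm": 10.0, "m": 1000.0}


def read_trc(path: str | Path) -> MarkerFrameSeries:
    """Read a TRC marker-trajectory file.

    Header fields ``DataRate``, ``NumFrames``, ``NumMarkers`` and ``Units``
    are honoured; positions are converted to millimetres. Blank coordinate
    cells become missing samples.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 5:
        raise FormatError(f"{path}: truncated TRC file ({len(lines)} lines)")

    header_keys = lines[1].rstrip("\n").split("\t")
    header_vals = lines[2].rstrip("\n").split("\t")
    header = dict(zip(header_keys, header_vals))
    for key in ("DataRate", "NumFrames", "NumMarkers", "Units"):
        if key not in header or header[key] == "":
            raise FormatError(f"{path}: line 2/3: missing TRC header field {key!r}")
    try:
        frame_rate = float(header["DataRate"])
        n_frames = int(header["NumFrames"])
        n_markers = int(header["NumMarkers"])
    except ValueError as exc:
        raise FormatError(f"{path}: line 3: bad numeric header value ({exc})") from None
    units = header["Units"].strip().lower()
    if units not in _UNIT_TO_MM:
        raise FormatError(f"{path}: line 3: unsupported Units {units!r}")
    scale = _UNIT_TO_MM[units]

    label_cells = lines[3].rstrip("\n").split("\t")
    labels = [c.strip() for c in label_cells[2:] if c.strip()]
    if len(labels) != n_markers:
        raise FormatError(
            f"{path}: line 4: {len(labels)} labels but header says {n_markers} markers"
        )

    positions = np.full((n_markers, n_frames, 3), np.nan)
    missing = np.ones((n_markers, n_frames), dtype=bool)
    n_cols = 2 + 3 * n_markers
    frame = 0
    for lineno, line in enumerate(lines[4:], start=5):
        stripped = line.strip()
        if not stripped or stripped.startswith("X1"):
            continue  # component row / blank separator
        cells = line.rstrip("\n").split("\t")
        if len(cells) < n_cols:
            cells = cells + [""] * (n_cols - len(cells))
        elif len(cells) > n_cols:
            raise FormatError(
                f"{path}: frame index {frame} (line {lineno}): "
                f"{len(cells)} columns, expected {n_cols}"
            )
        if frame >= n_frames:
            raise FormatError(f"{path}: more data rows than NumFrames={n_frames}")
        for m in range(n_markers):
            triple = cells[2 + 3 * m : 5 + 3 * m]
            if any(c.strip() == "" for c in triple):
                continue
            try:
                positions[m, frame] = [float(c) for c in triple]
            except ValueError:
                raise FormatError(
                    f"{path}: frame index {frame} (line {lineno}): "
                    f"non-numeric coordinate for marker {labels[m]!r}"
                ) from None
            missing[m, frame] = False
        frame += 1
    if frame != n_frames:
        raise FormatError(f"{path}: {frame} data rows, header says NumFrames={n_frames}")
    positions *= scale
    return MarkerFrameSeries(labels, frame_rate, positions, missing)


def write_trc(series: MarkerFrameSeries, path: str | Path, units: str = "mm") -> None:
    """Write ``series`` as a TRC file. Missing samples become blank cells."""
    path = Path(path)
    if units not in _UNIT_TO_MM:
        raise ValueError(f"unsupported units {units!r}")
    scale = 1.0 / _UNIT_TO_MM[units]
    n_dec = 5 if units == "m" else 3
    rows = []
    rows.append(f"PathFileType\t4\t(X/Y/Z)\t{path.name}")
    rows.append(
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
        "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames"
    )
    rows.append(
        f"{series.frame_rate:g}\t{series.frame_rate:g}\t{series.n_frames}\t"
        f"{series.n_markers}\t{units}\t{series.frame_rate:g}\t1\t{series.n_frames}"
    )
    rows.append("Frame#\tTime\t" + "\t\t\t".join(series.marker_labels) + "\t\t")
    comp = "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(series.n_markers))
    rows.append("\t\t" + comp)
    rows.append("")
    times = series.times
    for f in range(series.n_frames):
        cells = [str(f + 1), f"{times[f]:.5f}"]
        for m in range(series.n_markers):
            if series.missing[m, f]:
                cells.extend(["", "", ""])
            else:
                cells.extend(f"{v * scale:.{n_dec}f}" for v in series.positions[m, f])
        rows.append("\t".join(cells))
    path.write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# CSV (long format: frame,time,marker,x,y,z,missing)
# ---------------------------------------------------------------------------

def write_csv(series: MarkerFrameSeries, path: str | Path) -> None:
    """Write the series in long CSV format (one row per marker per frame)."""
    times = series.times
    records = []
    for m, label in enumerate(series.marker_labels):
        for f in range(series.n_frames):
            x, y, z = series.positions[m, f]
            records.append(
                {
                    "frame": f,
                    "time": times[f],
                    "marker": label,
                    "x": x,
                    "y": y,
                    "z": z,
                    "missing": bool(series.missing[m, f]),
                }
            )
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def read_csv(path: str | Path) -> MarkerFrameSeries:
    """Read a long-format CSV written by :func:`write_csv`."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"frame", "time", "marker", "x", "y", "z", "missing"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: missing CSV columns {sorted(required - set(df.columns))}"
        )
    labels = list(dict.fromkeys(df["marker"].astype(str)))
    frames = np.sort(df["frame"].unique())
    n_frames = len(frames)
    if not np.array_equal(frames, np.arange(n_frames)):
        raise FormatError(f"{path}: frame indices must be contiguous from 0")
    per_frame = df.groupby("frame")["time"].first().sort_index().to_numpy()
    if n_frames > 1:
        dt = np.diff(per_frame)
        if not np.allclose(dt, dt[0], atol=1e-9):
            raise FormatError(f"{path}: non-uniform sampling times")
        frame_rate = 1.0 / dt[0]
    else:
        frame_rate = 200.0
    positions = np.full((len(labels), n_frames, 3), np.nan)
    missing = np.ones((len(labels), n_frames), dtype=bool)
    idx = {lb: i for i, lb in enumerate(labels)}
    for row in df.itertuples(index=False):
        m = idx[str(row.marker)]
        f = int(row.frame)
        if bool(row.missing):
            continue
        positions[m, f] = (row.x, row.y, row.z)
        missing[m, f] = False
    return MarkerFrameSeries(labels, frame_rate, positions, missing)


# ---------------------------------------------------------------------------
# C3D (binary; optional — requires the ezc3d extra)
# ---------------------------------------------------------------------------

def _require_ezc3d():
    try:
        import ezc3d  # type: ignore
    except ImportError as exc:
        raise FormatError(
            "C3D support requires the optional 'ezc3d' dependency "
            "(pip install kinerisk[c3d]); TRC and CSV readers need no extras"
        ) from exc
    return ezc3d


def read_c3d(path: str | Path) -> MarkerFrameSeries:
    """Read a C3D file; residual-flagged invalid samples become missing."""
    ezc3d = _require_ezc3d()
    try:
        c3d = ezc3d.c3d(str(path))
    except Exception as exc:  # ezc3d raises plain RuntimeError on bad bytes
        raise FormatError(f"{path}: unreadable C3D file ({exc})") from exc
    pts = c3d["data"]["points"]  # (4, n_markers, n_frames)
    labels = list(c3d["parameters"]["POINT"]["LABELS"]["value"])
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    unit = str(c3d["parameters"]["POINT"]["UNITS"]["value"][0]).strip().lower()
    scale = _UNIT_TO_MM.get(unit, 1.0)
    positions = np.transpose(pts[:3], (1, 2, 0)) * scale
    residuals = c3d["data"]["meta_points"]["residuals"][0]
    missing = (residuals < 0) | ~np.all(np.isfinite(positions), axis=2)
    positions = np.where(missing[:, :, None], np.nan, positions)
    return MarkerFrameSeries(labels, rate, positions, missing)


def write_c3d(series: MarkerFrameSeries, path: str | Path) -> None:
    """Write the series to C3D (requires the ezc3d extra)."""
    ezc3d = _require_ezc3d()
    c3d = ezc3d.c3d()
    c3d["parameters"]["POINT"]["RATE"]["value"] = [series.frame_rate]
    c3d["parameters"]["POINT"]["LABELS"]["value"] = list(series.marker_labels)
    c3d["parameters"]["POINT"]["UNITS"]["value"] = ["mm"]
    pts = np.ones((4, series.n_markers, series.n_frames))
    pts[:3] = np.transpose(np.where(series.missing[:, :, None], 0.0, series.positions), (2, 0, 1))
    c3d["data"]["points"] = pts
    residuals = np.where(series.missing, -1.0, 0.0)[None, :, :]
    c3d["data"]["meta_points"]["residuals"] = residuals
    c3d.write(str(path))


def write_report_json(report: dict, path: str | Path) -> None:
    """Serialize a pipeline report dictionary to JSON."""

    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(report, indent=2, default=_default) + "\n")
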
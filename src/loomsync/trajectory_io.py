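"""Tracking-table input, pixel calibration, and velocity-matrix assembly.

The analysis window of one trial is 30 s sampled at 5 fps: three 10-s
intervals (before / during / after the looming stimulus), i.e. 150 frames
split as [0, 50), [50, 100), [100, 150).  Raw tracker output is one row per
frame with an x/y column pair per individual, in pixels or centimetres.
Speeds are frame-to-frame Euclidean displacements times the frame rate,
smoothed with a trailing moving average (window 5, partial leading windows)
so the series keeps all 150 frames.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ANALYSIS_FPS = 5
INTERVAL_S = 10
N_INTERVALS = 3
FRAMES_PER_INTERVAL = ANALYSIS_FPS * INTERVAL_S  # 50
N_FRAMES = FRAMES_PER_INTERVAL * N_INTERVALS  # 150

#: Half-open frame ranges of the three analysis intervals.
INTERVALS: dict[str, slice] = {
    "before": slice(0, FRAMES_PER_INTERVAL),
    "during": slice(FRAMES_PER_INTERVAL, 2 * FRAMES_PER_INTERVAL),
    "after": slice(2 * FRAMES_PER_INTERVAL, N_FRAMES),
}

INTERVAL_NAMES = tuple(INTERVALS)


class TrackingParseError(ValueError):
    """A tracking CSV violates the dialect or an invariant."""


class CalibrationError(ValueError):
    """Invalid pixel-to-cm calibration."""


_COORD_RE = re.compile(r"^id(\d+)_(x|y)$")


@dataclass
class CalibrationSpec:
    """Pixel-to-centimetre conversion measured off the tank's inner long side.

    ``pixels_per_cm`` is the pixel span of the long side divided by its
    physical inner length (20.0-20.5 cm depending on the tank).
    """

    pixels_per_cm: float
    source_length_cm: float | None = None

    def __post_init__(self) -> None:
        if not self.pixels_per_cm > 0:
            raise CalibrationError(
                f"pixels_per_cm must be positive, got {self.pixels_per_cm}"
            )

    @classmethod
    def from_span(cls, span_px: float, source_length_cm: float) -> "CalibrationSpec":
        if source_length_cm <= 0:
            raise CalibrationError("source_length_cm must be positive")
        return cls(span_px / source_length_cm, source_length_cm)


@dataclass
class TrackingTable:
    """Per-frame x/y coordinates for every individual of one group-trial.

    ``data`` holds a ``frame`` column plus ``id{i}_x``/``id{i}_y`` pairs;
    the video convention is origin top-left, y increasing downward.
    """

    data: pd.DataFrame
    units: str = "cm"  # "cm" or "px"
    group_id: str | int | None = None
    trial_id: int | None = None
    condition: str | None = None
    fps: int = ANALYSIS_FPS

    def __post_init__(self) -> None:
        self.validate()

    @property
    def individuals(self) -> list[int]:
        ids = sorted(
            {int(m.group(1)) for c in self.data.columns if (m := _COORD_RE.match(c))}
        )
        return ids

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_frames(self) -> int:
        return len(self.data)

    def coords(self, individual: int) -> np.ndarray:
        """(n_frames, 2) array of x/y for one individual."""
        return self.data[[f"id{individual}_x", f"id{individual}_y"]].to_numpy(float)

    def validate(self) -> None:
        df = self.data
        if "frame" not in df.columns:
            raise TrackingParseError("missing 'frame' column")
        if self.units not in ("cm", "px"):
            raise TrackingParseError(f"unknown units flag {self.units!r}")
        ids = self.individuals
        if not ids:
            raise TrackingParseError("no id{i}_x/id{i}_y coordinate columns found")
        for i in ids:
            for ax in ("x", "y"):
                col = f"id{i}_{ax}"
                if col not in df.columns:
                    raise TrackingParseError(f"missing column {col!r}")
                bad = df.index[df[col].isna()]
                if len(bad):
                    raise TrackingParseError(
                        f"NaN coordinate in column {col!r} at row {int(bad[0])}"
                    )
        frames = df["frame"].to_numpy()
        step = np.diff(frames)
        if np.any(step <= 0):
            row = int(np.argmax(step <= 0))
            raise TrackingParseError(f"non-monotone frame index at row {row + 1}")
        if np.any(step > 1):
            row = int(np.argmax(step > 1))
            raise TrackingParseError(
                f"frame gap between rows {row} and {row + 1} "
                f"(frames {frames[row]} -> {frames[row + 1]})"
            )
        if len(df) < N_FRAMES:
            raise TrackingParseError(
                f"insufficient frames: got {len(df)}, need >= {N_FRAMES}"
            )


def read_tracking(path: str | Path, manifest: dict | str | Path | None = None) -> TrackingTable:
    """Read one tracking CSV, resolving metadata from a sidecar manifest.

    The manifest (``manifest.json`` next to the file unless given explicitly)
    maps file names to group/trial/condition and carries the units flag and
    frame rate.  Without a manifest the units default to cm.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if manifest is None:
        cand = path.parent / "manifest.json"
        if cand.exists():
            manifest = cand
    if isinstance(manifest, (str, Path)):
        manifest = json.loads(Path(manifest).read_text())

    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TrackingParseError(f"cannot parse {path}: {exc}") from exc

    units, group_id, trial_id, condition, fps = "cm", None, None, None, ANALYSIS_FPS
    if manifest:
        units = manifest.get("units", units)
        fps = manifest.get("fps", fps)
        for entry in manifest.get("files", []):
            if entry.get("file") == path.name:
                group_id = entry.get("group")
                trial_id = entry.get("trial")
                condition = entry.get("condition")
                break
    return TrackingTable(
        data=df, units=units, group_id=group_id, trial_id=trial_id,
        condition=condition, fps=fps,
    )


def calibrate(table: TrackingTable, cal: CalibrationSpec) -> TrackingTable:
    """Convert pixel coordinates to centimetres (no-op with warning on cm input)."""
    if table.units == "cm":
        warnings.warn("table already in cm; calibrate is a no-op", stacklevel=2)
        return table
    df = table.data.copy()
    for col in df.columns:
        if _COORD_RE.match(col):
            df[col] = df[col] / cal.pixels_per_cm
    return TrackingTable(
        data=df, units="cm", group_id=table.group_id, trial_id=table.trial_id,
        condition=table.condition, fps=table.fps,
    )


def compute_speed(table: TrackingTable) -> np.ndarray:
    """Raw speed series (cm/s), one row per individual.

    speed[i] is the Euclidean displacement from frame i-1 to i times the
    frame rate; the first frame duplicates the speed at frame 1 so every
    interval keeps its full frame count.
    """
    if table.units != "cm":
        raise ValueError("table is in pixel units: calibrate first")
    out = np.empty((table.n_individuals, table.n_frames))
    for r, ind in enumerate(table.individuals):
        xy = table.coords(ind)
        d = np.linalg.norm(np.diff(xy, axis=0), axis=1) * table.fps
        out[r, 1:] = d
        out[r, 0] = d[0] if len(d) else 0.0
    return out


def smooth_speed(raw: np.ndarray, window: int = 5) -> np.ndarray:
    """Trailing moving average with partial leading windows (length-preserving)."""
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    raw = np.asarray(raw, float)
    one_d = raw.ndim == 1
    arr = raw[None, :] if one_d else raw
    n = arr.shape[1]
    cs = np.cumsum(arr, axis=1)
    out = np.empty_like(arr)
    lead = min(window, n)
    counts = np.arange(1, lead + 1, dtype=float)
    out[:, :lead] = cs[:, :lead] / counts
    if n > window:
        out[:, window:] = (cs[:, window:] - cs[:, :-window]) / window
    return out[0] if one_d else out


@dataclass
class VelocityMatrix:
    """Smoothed speed matrix: one row per individual-trial, 150 columns.

    ``data`` is indexed by (group, trial, individual); ``conditions`` gives
    the condition label per row, aligned with the index.
    """

    data: pd.DataFrame
    conditions: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.data.shape[1] != N_FRAMES:
            raise ValueError(
                f"velocity matrix must have {N_FRAMES} columns, got {self.data.shape[1]}"
            )
        vals = self.data.to_numpy()
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError("speeds must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def interval(self, name: str) -> np.ndarray:
        """Speed block of one analysis interval (rows x 50)."""
        return self.data.to_numpy()[:, INTERVALS[name]]


def build_velocity_matrix(
    tables: list[TrackingTable],
    cal: CalibrationSpec | None = None,
    window: int = 5,
) -> VelocityMatrix:
    """Calibrate, differentiate, smooth, and stack all group-trials.

    Rows are ordered (group, trial, individual); a 17-group x 6-fish x
    10-trial design yields a 1020 x 150 matrix.
    """
    if not tables:
        raise ValueError("no tracking tables given")
    n_by_group: dict = {}
    rows, index, conds = [], [], []
    for t in sorted(tables, key=lambda t: (str(t.group_id), t.trial_id or 0)):
        if t.units == "px":
            if cal is None:
                raise CalibrationError(
                    f"table {t.group_id}/{t.trial_id} is in pixels and no "
                    "CalibrationSpec was given"
                )
            t = calibrate(t, cal)
        prev = n_by_group.setdefault(t.group_id, t.n_individuals)
        if prev != t.n_individuals:
            raise ValueError(
                f"group {t.group_id!r} has heterogeneous individual counts "
                f"({prev} vs {t.n_individuals})"
            )
        speeds = smooth_speed(compute_speed(t)[:, :N_FRAMES], window=window)
        for r, ind in enumerate(t.individuals):
            rows.append(speeds[r])
            index.append((t.group_id, t.trial_id, ind))
            conds.append(t.condition)
    idx = pd.MultiIndex.from_tuples(index, names=["group", "trial", "individual"])
    data = pd.DataFrame(np.asarray(rows), index=idx, columns=range(N_FRAMES))
    return VelocityMatrix(data=data, conditions=pd.Series(conds, index=idx, name="condition"))
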
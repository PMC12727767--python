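"""Frame-level behaviour types and 10-s interval states.

Each smoothed speed frame is typed by two thresholds: freezing-like below
0.2 cm/s (strict), high-speed at or above 6 cm/s (inclusive), normal
swimming in between.  Each 10-s interval then receives one state:

* HS (high-speed state) if high-speed swimming is sustained for >= 0.2 s
  (one frame at 5 fps) -- the detection rule for a rapid escape burst;
* FS (freezing-like state) if freezing-like behaviour persists >= 8 s;
* NS (normal state) otherwise, which covers both the stated "< 2 s
  freezing" rule and the 2-8 s gap, keeping the three-state space
  exhaustive.

Precedence when criteria co-occur defaults to HS > FS > NS, and the 8-s
rule reads freezing duration as the total within the interval; both are
configurable since either convention is defensible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .trajectory_io import FRAMES_PER_INTERVAL, VelocityMatrix

# frame-type codes
FREEZE, NORMAL, HIGH = 0, 1, 2
FRAME_TYPE_NAMES = {FREEZE: "freeze", NORMAL: "normal", HIGH: "high"}


@dataclass
class ThresholdSpec:
    """Speed and duration thresholds defining behavioural types and states."""

    v_freeze: float = 0.2  # cm/s, strict upper bound of freezing-like frames
    v_high: float = 6.0  # cm/s, inclusive lower bound of high-speed frames
    fs_min_s: float = 8.0  # min freezing duration for FS
    ns_max_s: float = 2.0  # freezing duration below which NS is unambiguous
    hs_min_s: float = 0.2  # min sustained high-speed duration for HS
    fps: int = 5
    freeze_duration: str = "total"  # or "consecutive"
    precedence: tuple[str, ...] = ("HS", "FS", "NS")
    derived: bool = False  # True when produced by derive_thresholds
    fallback: bool = False  # True when derive_thresholds fell back to defaults

    def __post_init__(self) -> None:
        if not 0 < self.v_freeze < self.v_high:
            raise ValueError("need 0 < v_freeze < v_high")
        if not self.ns_max_s < self.fs_min_s:
            raise ValueError("need ns_max_s < fs_min_s")
        if self.hs_min_s < 1.0 / self.fps:
            raise ValueError("hs_min_s must cover at least one frame")
        if self.freeze_duration not in ("total", "consecutive"):
            raise ValueError(f"unknown freeze_duration {self.freeze_duration!r}")
        if sorted(self.precedence) != ["FS", "HS", "NS"]:
            raise ValueError("precedence must be a permutation of (FS, NS, HS)")


@dataclass
class IntervalState:
    """State of one 10-s interval plus the evidence it was based on."""

    value: str  # "FS" | "NS" | "HS"
    freeze_s: float  # freezing duration used by the rule (total or longest run)
    high_frames: int


def label_frames(speeds: np.ndarray, th: ThresholdSpec | None = None) -> np.ndarray:
    """Type each frame from its smoothed speed: 0=freeze, 1=normal, 2=high."""
    th = th or ThresholdSpec()
    speeds = np.asarray(speeds, float)
    if np.any(~np.isfinite(speeds)) or np.any(speeds < 0):
        raise ValueError("speeds must be finite and non-negative (upstream bug)")
    out = np.full(speeds.shape, NORMAL, dtype=np.int8)
    out[speeds < th.v_freeze] = FREEZE
    out[speeds >= th.v_high] = HIGH
    return out


def _longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for m in mask:
        cur = cur + 1 if m else 0
        best = max(best, cur)
    return best


def classify_interval(frames: np.ndarray, th: ThresholdSpec | None = None) -> IntervalState:
    """Assign FS/NS/HS to one interval of frame-type labels."""
    th = th or ThresholdSpec()
    frames = np.asarray(frames)
    expect = int(round(th.fps * 10))
    if len(frames) != expect:
        raise ValueError(f"interval must have {expect} frames, got {len(frames)}")
    freeze_mask = frames == FREEZE
    if th.freeze_duration == "total":
        freeze_frames = int(freeze_mask.sum())
    else:
        freeze_frames = _longest_run(freeze_mask)
    high_frames = int((frames == HIGH).sum())
    freeze_s = freeze_frames / th.fps

    met = {
        "HS": high_frames >= int(round(th.hs_min_s * th.fps)),
        "FS": freeze_frames >= int(round(th.fs_min_s * th.fps)),
        "NS": True,
    }
    for state in th.precedence:
        if met[state]:
            return IntervalState(value=state, freeze_s=freeze_s, high_frames=high_frames)
    raise AssertionError("unreachable: NS always applies")


def classify_trial(speeds: np.ndarray, th: ThresholdSpec | None = None) -> tuple[str, str, str]:
    """Classify one 150-frame smoothed speed row into its (before, during, after) triple."""
    th = th or ThresholdSpec()
    speeds = np.asarray(speeds, float)
    fpi = int(round(th.fps * 10))
    if len(speeds) != 3 * fpi:
        raise ValueError(f"trial must have {3 * fpi} frames, got {len(speeds)}")
    labels = label_frames(speeds, th)
    return tuple(
        classify_interval(labels[k * fpi : (k + 1) * fpi], th).value for k in range(3)
    )


def classify_velocity_matrix(vm: VelocityMatrix, th: ThresholdSpec | None = None):
    """State triples for every individual-trial row of a velocity matrix.

    Returns a DataFrame with group/trial/individual/condition and the three
    interval states plus provenance columns (freeze seconds and high-speed
    frame counts per interval, serialised as F/N/H-friendly strings).
    """
    import pandas as pd

    th = th or ThresholdSpec()
    fpi = FRAMES_PER_INTERVAL
    rows = []
    values = vm.data.to_numpy()
    for r, (g, t, i) in enumerate(vm.data.index):
        labels = label_frames(values[r], th)
        states = [classify_interval(labels[k * fpi : (k + 1) * fpi], th) for k in range(3)]
        rows.append(
            (
                g, t, i, vm.conditions.iloc[r],
                states[0].value, states[1].value, states[2].value,
                states[2].freeze_s, sum(s.high_frames for s in states),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group", "trial", "individual", "condition",
            "before", "during", "after", "freeze_s", "high_frames",
        ],
    )


def derive_thresholds(
    vm: VelocityMatrix,
    peak_fraction: float = 0.01,
    bw_method: float | str = 0.05,
    grid_size: int = 2048,
) -> ThresholdSpec:
    """Derive the two speed thresholds from the data, as the study did.

    * ``v_freeze``: the post-LS speed histogram is bimodal (freezing vs
      swimming); the threshold is the minimum of a Gaussian KDE between its
      two largest modes.
    * ``v_high``: the smallest speed above the pre-LS KDE's peak at which the
      density falls below ``peak_fraction`` of the peak (pre-LS swimming and
      escape bursts barely overlap beyond that point).

    Falls back to the canonical (0.2, 6.0) with a warning whenever the modes
    are not separable.  The default bandwidth (0.05 cm/s) is narrow enough to
    resolve the sub-0.2 cm/s freezing mode against the swimming mode.
    """
    if vm.shape[0] < 2:
        raise ValueError("need at least 2 velocity rows")
    post = vm.interval("after").ravel()
    pre = vm.interval("before").ravel()

    def _fallback(reason: str) -> ThresholdSpec:
        warnings.warn(f"derive_thresholds fallback to (0.2, 6.0): {reason}", stacklevel=3)
        return ThresholdSpec(derived=True, fallback=True)

    if np.ptp(post) <= 0 or np.ptp(pre) <= 0:
        return _fallback("degenerate (constant) speeds")

    grid = np.linspace(0.0, float(post.max()), grid_size)
    try:
        dens = gaussian_kde(post, bw_method=bw_method)(grid)
    except Exception as exc:
        return _fallback(f"post-LS KDE failed ({exc})")
    interior = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] > dens[2:])
    peaks = np.flatnonzero(interior) + 1
    if len(peaks) < 2:
        return _fallback("post-LS speed density is not bimodal")
    top2 = np.sort(peaks[np.argsort(dens[peaks])[-2:]])
    trough = top2[0] + int(np.argmin(dens[top2[0] : top2[1] + 1]))
    # genuine bimodality: the trough must dip well below the smaller mode,
    # otherwise the "modes" are just ripples of a unimodal density
    if dens[trough] > 0.5 * min(dens[top2[0]], dens[top2[1]]):
        return _fallback("post-LS speed density is not bimodal")
    v_freeze = float(grid[trough])

    pre_grid = np.linspace(0.0, float(pre.max()) * 1.5, grid_size)
    try:
        pre_dens = gaussian_kde(pre, bw_method=bw_method)(pre_grid)
    except Exception as exc:
        return _fallback(f"pre-LS KDE failed ({exc})")
    # reference peak = the swimming mode: pre-LS data may contain a tall
    # freezing mode, but the overlap criterion compares swimming vs bursts
    swim = pre_grid > v_freeze
    if not swim.any():
        return _fallback("no pre-LS density above the freezing trough")
    peak = int(np.flatnonzero(swim)[np.argmax(pre_dens[swim])])
    below = np.flatnonzero(pre_dens[peak:] < peak_fraction * pre_dens[peak])
    if not len(below):
        return _fallback("pre-LS density never falls below the peak fraction")
    v_high = float(pre_grid[peak + below[0]])
    if not v_freeze < v_high:
        return _fallback("derived thresholds are not ordered")
    return ThresholdSpec(v_freeze=v_freeze, v_high=v_high, derived=True)
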
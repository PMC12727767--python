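"""Agent-based generator of tank-swimming trajectories with known states.

The study's raw tracking data are not deposited, so every downstream stage
is exercised on simulated experiments with the same design: groups of six
medaka in a 20.25 x 14.5 cm arena, ten looming-stimulus (LS) trials per
group, 17 groups under the familiar condition (12 unfamiliar), recorded at
5 fps over three 10-s intervals (before / during / after LS).

Speed structure (trimodal, mirroring the empirical velocity histograms):

* freezing: near-immobile jitter, per-frame speed capped at ``v_freeze_max``
  (default 0.05 cm/s, well under the 0.2 cm/s freezing threshold);
* normal swimming: an AR(1) log-speed process (correlated random walk) with
  median ``v_normal_mean``, clipped to stay inside the (0.2, 6) cm/s band;
* escape bursts: three consecutive frames at ``v_burst`` during the LS
  interval.  The burst speed defaults to 12 cm/s because the classifier
  thresholds the *window-5 smoothed* series: three frames at 12 cm/s smooth
  to >= 7.2 cm/s, guaranteeing the high-speed state is detectable, whereas
  a single 8 cm/s frame would smooth to ~2.6 cm/s and vanish.

Group-level consensus is a two-stage draw.  Each group has an archetype
(freeze-dominant / non-freeze / mixed) setting a base log-odds of post-LS
freezing, plus a Gaussian group-level logit offset.  Stage one draws each
individual's independent freezing intent; stage two redraws freezing with
the logit shifted by ``coupling`` times the majority signal
(2 x intent fraction - 1).  ``coupling = 0`` gives independent individuals;
``coupling = inf`` forces the whole group onto the majority intent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .trajectory_io import ANALYSIS_FPS, TrackingTable

STATES = ("FS", "NS", "HS")

# Autocorrelation of the log-speed AR(1) process for normal swimming: high
# enough that multi-frame "darts" survive the window-5 smoothing, so the
# smoothed pre-LS speed distribution keeps a tail reaching toward 6 cm/s.
NORMAL_LOG_RHO = 0.9
# Normal-swim speeds are clipped clear of both classification thresholds.
NORMAL_CLIP = (0.22, 5.8)
# Escape bursts span this many consecutive frames.
BURST_FRAMES = 3
# Probability that an individual frozen before LS stays frozen through an
# LS interval it does not escape from.
P_STAY_FROZEN_DURING = 0.5


class ConfigError(ValueError):
    """A SimConfig field violates its invariant."""


@dataclass(frozen=True)
class Archetype:
    """A group behavioural type: mixture weight plus logit offsets.

    ``freeze_logit`` is the base log-odds that an individual of such a group
    freezes after LS; ``escape_offset`` shifts the log-odds of an escape
    burst during LS relative to ``p_escape_base``; ``coupling_scale``
    multiplies the experiment-wide ``coupling`` for groups of this type --
    the mixed profile shows no all-or-none synchrony (its FS counts spread
    over low values instead of piling at 0 and 6), so it is uncoupled.
    """

    name: str
    weight: float
    freeze_logit: float
    escape_offset: float
    coupling_scale: float = 1.0
    #: before-LS freezing probability; None falls back to SimConfig.p_fs_before.
    #: Both extreme profiles show prominent FS-before patterns (F->H->F,
    #: F->N->N) while the mixed profile's signature patterns all start from
    #: NS, so the mixed rate is low.
    p_fs_before: float | None = None


#: Default mixture: the three group response profiles seen in familiar groups
#: (freeze-dominant, non-freeze, mixed).
DEFAULT_TRAIT_MIX = (
    Archetype("freeze-dominant", 0.35, 2.2, 1.5, 1.0, 0.35),
    Archetype("non-freeze", 0.35, -2.2, -1.5, 1.0, 0.25),
    Archetype("mixed", 0.30, -1.0, 0.0, 0.0, 0.10),
)

#: Unfamiliar groups lack the freeze-dominant profile and couple weakly.
UNFAMILIAR_TRAIT_MIX = (
    Archetype("non-freeze", 0.60, -2.2, -1.5, 1.0, 0.25),
    Archetype("mixed", 0.40, -1.0, 0.0, 0.0, 0.10),
)


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, float)))


@dataclass
class SimConfig:
    """Full parameterisation of one simulated looming-stimulus experiment."""

    n_groups: int = 17
    n_individuals: int = 6
    n_trials: int = 10
    fps: int = ANALYSIS_FPS
    interval_s: float = 10.0
    arena_w: float = 20.25  # midpoint of the 20.0-20.5 cm inner length
    arena_h: float = 14.5
    v_normal_mean: float = 1.2  # median normal-swim speed, cm/s
    v_normal_sd: float = 1.0  # stationary sd of normal-swim speed, cm/s
    v_freeze_max: float = 0.05
    v_burst: float = 12.0
    p_escape_base: float = 0.4
    p_freeze_after_escape: float = 0.7
    p_fs_before: float = 0.2
    coupling: float = 3.0
    group_logit_sd: float = 0.25
    group_trait_mix: tuple[Archetype, ...] = DEFAULT_TRAIT_MIX
    #: optional explicit archetype name per group ("planted" designs for
    #: recovery tests); None draws archetypes from the mixture weights
    archetype_assignment: tuple[str, ...] | None = None
    condition: str = "familiar"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_groups", "n_individuals", "n_trials", "fps"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be a positive count")
        for name in ("p_escape_base", "p_freeze_after_escape", "p_fs_before"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if not (self.v_freeze_max < 0.2 < self.v_normal_mean < 6.0 <= self.v_burst):
            raise ConfigError(
                "speed modes must satisfy v_freeze_max < 0.2 < v_normal_mean"
                f" < 6 <= v_burst, got ({self.v_freeze_max}, {self.v_normal_mean},"
                f" {self.v_burst})"
            )
        if self.arena_w <= 0 or self.arena_h <= 0:
            raise ConfigError("arena_w and arena_h must be positive")
        if self.coupling < 0:
            raise ConfigError("coupling must be >= 0")
        if self.group_logit_sd < 0:
            raise ConfigError("group_logit_sd must be >= 0")
        if abs(self.fps * self.interval_s - round(self.fps * self.interval_s)) > 1e-9:
            raise ConfigError("fps x interval_s must be an integer frame count")
        if not self.group_trait_mix:
            raise ConfigError("group_trait_mix must list at least one archetype")
        if any(a.weight < 0 for a in self.group_trait_mix) or not any(
            a.weight > 0 for a in self.group_trait_mix
        ):
            raise ConfigError("group_trait_mix weights must be non-negative, not all zero")
        if self.archetype_assignment is not None:
            names = {a.name for a in self.group_trait_mix}
            if len(self.archetype_assignment) != self.n_groups:
                raise ConfigError("archetype_assignment must list one archetype per group")
            unknown = set(self.archetype_assignment) - names
            if unknown:
                raise ConfigError(f"archetype_assignment names unknown archetypes {unknown}")

    # -- presets -----------------------------------------------------------

    @classmethod
    def familiar(cls, **kw) -> "SimConfig":
        """The familiar-condition design: 17 groups, three archetypes, strong coupling."""
        return cls(**kw)

    @classmethod
    def unfamiliar(cls, **kw) -> "SimConfig":
        """Unfamiliar design: 12 groups, no freeze-dominant archetype, weak coupling."""
        kw.setdefault("n_groups", 12)
        kw.setdefault("group_trait_mix", UNFAMILIAR_TRAIT_MIX)
        kw.setdefault("coupling", 1.0)
        kw.setdefault("condition", "unfamiliar")
        return cls(**kw)

    @classmethod
    def independent(cls, q: float = 0.5, **kw) -> "SimConfig":
        """Homogeneous, uncoupled groups: every individual freezes after LS
        with the same independent probability ``q`` (the exchangeable null of
        the group-synchrony test)."""
        kw.setdefault(
            "group_trait_mix", (Archetype("iid", 1.0, _logit(min(max(q, 1e-9), 1 - 1e-9)), 0.0),)
        )
        kw.setdefault("coupling", 0.0)
        kw.setdefault("group_logit_sd", 0.0)
        kw.setdefault("p_escape_base", 0.0)
        kw.setdefault("condition", "independent")
        return cls(**kw)


@dataclass
class GroundTruth:
    """Intended state triples per individual-trial plus group archetypes."""

    triples: pd.DataFrame  # group, trial, individual, before, during, after, escaped
    archetypes: pd.Series  # index: group id -> archetype name
    condition: str = "familiar"


# ---------------------------------------------------------------------------
# State-level simulation (the statistical core; trajectories realise it)
# ---------------------------------------------------------------------------


def simulate_states(cfg: SimConfig, rng: np.random.Generator | None = None) -> GroundTruth:
    """Draw ground-truth state triples for every individual-trial.

    Before LS an individual is FS with probability ``p_fs_before`` else NS.
    During LS it escapes (HS) with an archetype-shifted probability; frozen
    non-escapers may stay FS.  After LS, freezing follows the two-stage
    consensus draw described in the module docstring.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    weights = np.array([a.weight for a in cfg.group_trait_mix], float)
    weights = weights / weights.sum()
    esc_base_logit = (
        _logit(min(max(cfg.p_escape_base, 1e-9), 1 - 1e-9)) if 0 < cfg.p_escape_base < 1
        else (-np.inf if cfg.p_escape_base == 0 else np.inf)
    )
    freeze_bonus = _logit(min(max(cfg.p_freeze_after_escape, 1e-9), 1 - 1e-9))

    by_name = {a.name: a for a in cfg.group_trait_mix}
    rows = []
    arch_names = []
    n = cfg.n_individuals
    for g in range(cfg.n_groups):
        if cfg.archetype_assignment is not None:
            arch = by_name[cfg.archetype_assignment[g]]
        else:
            arch = cfg.group_trait_mix[rng.choice(len(weights), p=weights)]
        arch_names.append(arch.name)
        g_eff = rng.normal(0.0, cfg.group_logit_sd) if cfg.group_logit_sd > 0 else 0.0
        p_escape = float(_sigmoid(esc_base_logit + arch.escape_offset))
        p_before = cfg.p_fs_before if arch.p_fs_before is None else arch.p_fs_before
        for t in range(cfg.n_trials):
            before = np.where(rng.random(n) < p_before, "FS", "NS")
            escaped = rng.random(n) < p_escape
            stay_frozen = (
                (before == "FS") & ~escaped & (rng.random(n) < P_STAY_FROZEN_DURING)
            )
            during = np.where(escaped, "HS", np.where(stay_frozen, "FS", "NS"))
            base = arch.freeze_logit + g_eff + np.where(escaped, freeze_bonus, 0.0)
            intent = rng.random(n) < _sigmoid(base)
            frac = intent.mean()
            if np.isinf(cfg.coupling):
                # infinite conformity dominates any archetype coupling scale
                if frac > 0.5:
                    final = np.ones(n, bool)
                elif frac < 0.5:
                    final = np.zeros(n, bool)
                else:  # exact tie: one shared draw at the group's base rate
                    final = np.full(n, rng.random() < float(_sigmoid(base.mean())))
            else:
                signal = 2.0 * frac - 1.0
                eff = cfg.coupling * arch.coupling_scale
                final = rng.random(n) < _sigmoid(base + eff * signal)
            after = np.where(final, "FS", "NS")
            for i in range(n):
                rows.append((g, t, i, before[i], during[i], after[i], bool(escaped[i])))
    triples = pd.DataFrame(
        rows, columns=["group", "trial", "individual", "before", "during", "after", "escaped"]
    )
    archetypes = pd.Series(arch_names, index=range(cfg.n_groups), name="archetype")
    return GroundTruth(triples=triples, archetypes=archetypes, condition=cfg.condition)


def simulate_fs_counts(
    n_groups: int,
    n_trials: int,
    base_logit: float,
    effect_logit: float = 0.0,
    group_sd: float = 0.5,
    n_individuals: int = 6,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-trial FS counts from a plain binomial-logit mixed model.

    Used for parameter-recovery simulations of the group-level GLMM: count
    ~ Binomial(n, logistic(base + effect + group intercept)).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    g_eff = rng.normal(0.0, group_sd, n_groups)
    p = _sigmoid(base_logit + effect_logit + g_eff)
    counts = rng.binomial(n_individuals, p[:, None], size=(n_groups, n_trials))
    recs = [
        (g, t, int(counts[g, t]), n_individuals)
        for g in range(n_groups)
        for t in range(n_trials)
    ]
    return pd.DataFrame(recs, columns=["group", "trial", "fs_count", "n"])


# ---------------------------------------------------------------------------
# Trajectory synthesis
# ---------------------------------------------------------------------------


def _reflect(x: np.ndarray | float, lo: float, hi: float):
    """Fold a coordinate back into [lo, hi] by specular reflection."""
    span = hi - lo
    y = np.mod(np.asarray(x, float) - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return y + lo


def _speed_profile(states: tuple[str, str, str], cfg: SimConfig, rng: np.random.Generator):
    """Commanded per-frame speeds (cm/s) for one 150-frame trial.

    Returns (speeds, burst_mask): burst frames are steered away from walls so
    the commanded displacement is realised even near a boundary.
    """
    fpi = int(cfg.fps * cfg.interval_s)
    n = fpi * len(states)
    speeds = np.empty(n)
    burst = np.zeros(n, bool)
    sigma = math.sqrt(math.log(1.0 + (cfg.v_normal_sd / cfg.v_normal_mean) ** 2))
    mu = math.log(cfg.v_normal_mean)
    # one continuous AR(1) log-speed path reused wherever the fish swims
    z = np.empty(n)
    z[0] = rng.normal()
    eps = rng.normal(size=n - 1) * math.sqrt(1 - NORMAL_LOG_RHO**2)
    for i in range(1, n):
        z[i] = NORMAL_LOG_RHO * z[i - 1] + eps[i - 1]
    swim = np.clip(np.exp(mu + sigma * z), *NORMAL_CLIP)
    freeze = np.clip(np.abs(rng.normal(0.0, cfg.v_freeze_max / 2, n)), 1e-4, cfg.v_freeze_max)

    for k, st in enumerate(states):
        sl = slice(k * fpi, (k + 1) * fpi)
        if st == "FS":
            speeds[sl] = freeze[sl]
        else:
            speeds[sl] = swim[sl]
            if st == "HS":
                # burst placed so its smoothing tail stays inside the interval
                off = int(rng.integers(2, fpi - BURST_FRAMES - 5))
                lo = k * fpi + off
                speeds[lo : lo + BURST_FRAMES] = cfg.v_burst
                burst[lo : lo + BURST_FRAMES] = True
    return speeds, burst


def simulate_trajectory(
    states: tuple[str, str, str],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One individual-trial path: (150, 2) positions inside the arena.

    The per-frame displacement times fps realises the commanded speed regime
    of the current interval; the path reflects off the arena walls.  Burst
    frames head toward the arena centre so reflections cannot fold the
    commanded escape displacement below the high-speed threshold.
    """
    if any(s not in STATES for s in states):
        raise ConfigError(f"invalid state triple {states!r}")
    speeds, burst = _speed_profile(states, cfg, rng)
    n = len(speeds)
    w, h = cfg.arena_w, cfg.arena_h
    pos = np.empty((n, 2))
    pos[0] = (rng.uniform(0.1 * w, 0.9 * w), rng.uniform(0.1 * h, 0.9 * h))
    heading = rng.uniform(0, 2 * math.pi)
    turn = rng.normal(0.0, 0.5, n)
    margin = 1.0
    for i in range(1, n):
        x, y = pos[i - 1]
        if burst[i] or (
            speeds[i] > cfg.v_freeze_max
            and (x < margin or x > w - margin or y < margin or y > h - margin)
        ):
            # aim toward the centre (tight cone for bursts, loose for avoidance)
            to_c = math.atan2(h / 2 - y, w / 2 - x)
            jitter = 0.4 if burst[i] else 0.9
            heading = to_c + rng.uniform(-jitter, jitter)
        else:
            heading += turn[i]
        step = speeds[i] / cfg.fps
        nx = x + step * math.cos(heading)
        ny = y + step * math.sin(heading)
        if not (0 <= nx <= w):
            nx = float(_reflect(nx, 0.0, w))
            heading = math.pi - heading
        if not (0 <= ny <= h):
            ny = float(_reflect(ny, 0.0, h))
            heading = -heading
        pos[i] = (nx, ny)
    return pos


def simulate_experiment(cfg: SimConfig) -> tuple[list[TrackingTable], GroundTruth]:
    """Full experiment: one TrackingTable per group-trial plus ground truth.

    Deterministic in ``cfg.seed``: identical configs give byte-identical
    coordinate tables.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    truth = simulate_states(cfg, rng)
    tables: list[TrackingTable] = []
    tri = truth.triples.set_index(["group", "trial", "individual"])
    fpi = int(cfg.fps * cfg.interval_s)
    n_frames = fpi * 3
    for g in range(cfg.n_groups):
        for t in range(cfg.n_trials):
            cols: dict[str, np.ndarray] = {"frame": np.arange(n_frames)}
            for i in range(cfg.n_individuals):
                row = tri.loc[(g, t, i)]
                path = simulate_trajectory(
                    (row["before"], row["during"], row["after"]), cfg, rng
                )
                cols[f"id{i}_x"] = path[:, 0]
                cols[f"id{i}_y"] = path[:, 1]
            tables.append(
                TrackingTable(
                    data=pd.DataFrame(cols), units="cm", group_id=g, trial_id=t,
                    condition=cfg.condition, fps=cfg.fps,
                )
            )
    return tables, truth


# ---------------------------------------------------------------------------
# Fixture output
# ---------------------------------------------------------------------------


def write_fixture(
    tables: list[TrackingTable],
    dir_path: str | Path,
    truth: GroundTruth | None = None,
    seed: int | None = None,
    pixels_per_cm: float | None = None,
) -> Path:
    """Write one CSV per group-trial plus a JSON manifest; returns manifest path.

    With ``pixels_per_cm`` the coordinates are exported in pixels (exercising
    the calibration path); otherwise they round-trip in cm.
    """
    if not tables:
        raise ValueError("no tables to write")
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    units = "px" if pixels_per_cm else "cm"
    entries = []
    for t in tables:
        name = f"g{int(t.group_id):03d}_t{int(t.trial_id):02d}.csv"
        df = t.data
        if pixels_per_cm:
            df = df.copy()
            for col in df.columns:
                if col != "frame":
                    df[col] = df[col] * pixels_per_cm
        # %.17g keeps every float64 bit so coordinates round-trip exactly
        df.to_csv(dir_path / name, index=False, float_format="%.17g")
        entry = {
            "file": name,
            "group": t.group_id,
            "trial": t.trial_id,
            "condition": t.condition,
        }
        if truth is not None:
            entry["archetype"] = str(truth.archetypes.get(t.group_id, ""))
        entries.append(entry)
    manifest = {
        "units": units,
        "fps": tables[0].fps,
        "seed": seed,
        "pixels_per_cm": pixels_per_cm,
        "n_files": len(entries),
        "files": entries,
    }
    path = dir_path / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path


def triples_from_truth(truth: GroundTruth) -> pd.DataFrame:
    """Ground-truth triples in the layout the analysis stages consume."""
    df = truth.triples[["group", "trial", "individual", "before", "during", "after"]].copy()
    df["condition"] = truth.condition
    return df
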
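"""Group-synchrony test: FS counts per trial against a shuffle null.

For each trial the number of individuals (out of six) in the freezing-like
state after LS is counted, giving a 7-bin histogram over 0-6.  The null
hypothesis -- each individual's FS is independent, group-level synchrony
arises by chance -- is materialised by seeded virtual datasets: within each
trial index, the FS indicators of all individuals are pooled across groups,
permuted, and reassigned to groups of six (1,000 replicates, seeds 1..1000
by default).  The observed histogram is compared with the replicate-averaged
null proportions by a chi-square test with df = 6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

GROUP_SIZE = 6


@dataclass
class FSCountHistogram:
    """Frequencies of 0..group_size FS individuals per trial."""

    counts: np.ndarray  # length group_size + 1
    total: int
    condition: str | None = None
    group_size: int = GROUP_SIZE

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.counts) != self.group_size + 1:
            raise ValueError(f"histogram must have {self.group_size + 1} bins")
        if self.counts.sum() != self.total:
            raise ValueError("bin frequencies must sum to the trial total")

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.total


@dataclass
class ShuffleConfig:
    """Replication scheme of the shuffle null."""

    n_replicates: int = 1000
    seeds: list[int] | None = None  # defaults to 1..n_replicates
    pool_scope: str = "within-trial-index"  # or "global"

    def __post_init__(self) -> None:
        if self.seeds is None:
            self.seeds = list(range(1, self.n_replicates + 1))
        if len(self.seeds) != self.n_replicates:
            raise ValueError("len(seeds) must equal n_replicates")
        if self.pool_scope not in ("within-trial-index", "global"):
            raise ValueError(f"unknown pool_scope {self.pool_scope!r}")


@dataclass
class NullDistribution:
    """Replicate-averaged null FS-count distribution (replicates retained)."""

    proportions: np.ndarray  # length 7, sums to 1
    replicate_counts: np.ndarray  # (n_replicates, 7)
    config: ShuffleConfig = field(repr=False, default=None)


@dataclass
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    merged: bool = False
    n_bins: int = 7


def fs_flags_from_triples(triples: pd.DataFrame) -> np.ndarray:
    """(n_groups, n_trials, group_size) boolean array of after-LS FS flags."""
    df = triples.sort_values(["group", "trial", "individual"])
    groups = df["group"].unique()
    trials = df["trial"].unique()
    inds = df["individual"].unique()
    arr = (df["after"] == "FS").to_numpy()
    try:
        return arr.reshape(len(groups), len(trials), len(inds))
    except ValueError as exc:
        raise ValueError("incomplete group/trial/individual design") from exc


def count_fs_per_trial(
    triples: pd.DataFrame, group_size: int = GROUP_SIZE, condition: str | None = None
) -> FSCountHistogram:
    """Histogram of the number of FS individuals per group-trial after LS."""
    sizes = triples.groupby(["group", "trial"])["individual"].count()
    bad = sizes[sizes != group_size]
    if len(bad):
        g, t = bad.index[0]
        raise ValueError(
            f"group {g!r} trial {t!r} has {bad.iloc[0]} individuals, expected {group_size}"
        )
    per_trial = (
        triples.assign(fs=triples["after"] == "FS")
        .groupby(["group", "trial"])["fs"]
        .sum()
        .astype(int)
    )
    counts = np.bincount(per_trial.to_numpy(), minlength=group_size + 1)
    if condition is None and "condition" in triples:
        uniq = triples["condition"].dropna().unique()
        condition = uniq[0] if len(uniq) == 1 else None
    return FSCountHistogram(
        counts=counts, total=len(per_trial), condition=condition, group_size=group_size
    )


def shuffle_null(fs_flags: np.ndarray | pd.DataFrame, cfg: ShuffleConfig | None = None) -> NullDistribution:
    """Seeded shuffle null of independent responding.

    For each replicate seed, the FS flags are pooled (across groups within
    each trial index by default, or globally), permuted uniformly, and
    reassigned to groups of six; the FS-count histogram of each replicate is
    retained and the per-bin proportions are averaged across replicates.
    Identical seeds give an identical null.
    """
    cfg = cfg or ShuffleConfig()
    if isinstance(fs_flags, pd.DataFrame):
        fs_flags = fs_flags_from_triples(fs_flags)
    flags = np.asarray(fs_flags, dtype=bool)
    if flags.ndim != 3:
        raise ValueError("fs_flags must be (n_groups, n_trials, group_size)")
    n_groups, n_trials, size = flags.shape
    if cfg.pool_scope == "within-trial-index" and n_groups < 2:
        raise ValueError("within-trial-index pooling needs at least 2 groups to shuffle across")
    n_bins = size + 1
    rep_counts = np.empty((cfg.n_replicates, n_bins), dtype=int)
    # (n_trials, n_groups*size): each row is one trial-index pool
    pooled = flags.transpose(1, 0, 2).reshape(n_trials, n_groups * size)
    for r, seed in enumerate(cfg.seeds):
        rng = np.random.default_rng(seed)
        if cfg.pool_scope == "within-trial-index":
            shuffled = rng.permuted(pooled, axis=1)
        else:
            shuffled = rng.permutation(pooled.ravel()).reshape(pooled.shape)
        counts = shuffled.reshape(n_trials, n_groups, size).sum(axis=2)
        rep_counts[r] = np.bincount(counts.ravel(), minlength=n_bins)
    props = rep_counts.mean(axis=0) / (n_groups * n_trials)
    return NullDistribution(proportions=props, replicate_counts=rep_counts, config=cfg)


def chi_square_compare(
    obs: FSCountHistogram, null: NullDistribution, merge_zero: bool = True
) -> ChiSquareResult:
    """Chi-square of the observed FS-count histogram against the null.

    Expected counts are the replicate-averaged null proportions times the
    observed trial total (plug-in), df = bins - 1 = 6.  Bins with zero
    expectation are merged into their neighbour (df reduced, flagged) unless
    ``merge_zero`` is False, in which case they raise.
    """
    if obs.total <= 0:
        raise ValueError("observed histogram is empty")
    O = obs.counts.astype(float)
    E = null.proportions * obs.total
    if np.any(E <= 0):
        if not merge_zero:
            raise ValueError("zero expected count in a bin; enable merge_zero or fix the null")
        O2, E2 = [], []
        acc_o = acc_e = 0.0
        for o, e in zip(O, E):
            acc_o += o
            acc_e += e
            if acc_e > 0:
                O2.append(acc_o)
                E2.append(acc_e)
                acc_o = acc_e = 0.0
        if acc_e > 0 or acc_o > 0:  # trailing zero-expectation bins fold backwards
            if not E2:
                raise ValueError("all expected counts are zero")
            O2[-1] += acc_o
            E2[-1] += acc_e
        O, E = np.asarray(O2), np.asarray(E2)
        merged = True
    else:
        merged = False
    stat = float(np.sum((O - E) ** 2 / E))
    df = len(O) - 1
    return ChiSquareResult(
        chi2=stat, df=df, p=float(chi2_dist.sf(stat, df)), merged=merged, n_bins=len(O)
    )
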
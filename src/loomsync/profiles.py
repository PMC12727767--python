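"""Group response profiles: features, reduction, clustering, and the GLMM.

Each group's profile is the relative frequency of the 27 transition
patterns over its 60 individual-trials (6 fish x 10 trials).  Profiles are
reduced by PCA to the smallest dimensionality explaining > 95% of the
variance (d95), embedded in 2-D with UMAP for inspection, and partitioned
by spectral clustering with the cluster number chosen by the silhouette
coefficient.  Clustering and silhouettes operate on the PCA scores; the
2-D embedding is visualisation only.

FS counts per group-trial (0-6 successes out of 6) are compared across
clusters / conditions with a binomial-logit generalized linear mixed model
fitted by maximum likelihood in lme4 (via Rscript), with Tukey-adjusted
pairwise contrasts from multcomp -- the same toolchain the field uses for
hierarchical count data of this shape.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import SpectralClustering
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .transitions import N_PATTERNS, PatternCode

DEFAULT_K_GRID = tuple(range(2, 7))


def build_group_features(triples: pd.DataFrame) -> pd.DataFrame:
    """Per-group 27-dim pattern-frequency matrix (rows sum to 1).

    Zero-count patterns are retained so every group lives in the same
    27-dim space.  A ``condition`` column is carried through when present.
    """
    sizes = triples.groupby("group")["individual"].count()
    if sizes.nunique() != 1:
        raise ValueError(f"groups have unequal designs: {sorted(sizes.unique())} rows per group")
    rows = {}
    conditions = {}
    for g, sub in triples.groupby("group"):
        counts = np.zeros(N_PATTERNS)
        for t in sub[["before", "during", "after"]].itertuples(index=False):
            counts[PatternCode.from_triple(tuple(t)).index] += 1
        rows[g] = counts / counts.sum()
        if "condition" in sub:
            conditions[g] = sub["condition"].iloc[0]
    feat = pd.DataFrame.from_dict(rows, orient="index", columns=range(N_PATTERNS))
    feat.index.name = "group"
    if conditions:
        feat.attrs["condition"] = pd.Series(conditions)
    return feat


def reduce_pca_95(features: pd.DataFrame | np.ndarray, threshold: float = 0.95):
    """PCA scores truncated at d95, the smallest d with cumulative explained
    variance ratio above the threshold.  Returns (scores, d95)."""
    X = np.asarray(features, float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows for PCA")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("zero variance: features are constant across groups")
    pca = PCA()
    scores = pca.fit_transform(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    d95 = int(np.searchsorted(cum, threshold) + 1)
    d95 = min(d95, scores.shape[1])
    return scores[:, :d95], d95


def embed_2d(
    scores: np.ndarray,
    seed: int = 0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> np.ndarray:
    """Deterministic 2-D UMAP embedding of the PCA scores (visualisation only)."""
    import umap  # deferred: heavy import

    scores = np.asarray(scores, float)
    n = scores.shape[0]
    if n < 4:
        raise ValueError("need at least 4 rows to embed")
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, n - 1),
        min_dist=min_dist,
        random_state=seed,
    )
    return np.asarray(reducer.fit_transform(scores))


@dataclass
class ClusterResult:
    """Spectral-clustering outcome with silhouette-based model selection."""

    labels: np.ndarray
    chosen_k: int
    silhouettes: dict[int, float]
    d95: int | None = None
    embedding: np.ndarray | None = None
    index: pd.Index | None = None

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"cluster": self.labels})
        if self.index is not None:
            df.index = self.index
        if self.embedding is not None:
            df["umap_x"] = self.embedding[:, 0]
            df["umap_y"] = self.embedding[:, 1]
        return df


def cluster_with_silhouette(
    scores: np.ndarray,
    k_grid=DEFAULT_K_GRID,
    seed: int = 0,
) -> ClusterResult:
    """Spectral clustering over a k grid; the k maximising the silhouette wins.

    The affinity is a symmetrised nearest-neighbours graph with ~sqrt(n)
    neighbours: with a few dozen groups, a denser graph would wire every
    point across cluster boundaries.  Silhouettes are computed in the same
    (PCA score) space the clustering sees.
    """
    scores = np.asarray(scores, float)
    n = scores.shape[0]
    k_grid = sorted(k_grid)
    if not k_grid or k_grid[0] < 2 or k_grid[-1] > n - 1:
        raise ValueError(f"k_grid must lie within [2, {n - 1}], got {k_grid}")
    sil: dict[int, float] = {}
    labels: dict[int, np.ndarray] = {}
    n_neighbors = min(max(3, round(n**0.5)), n - 1)
    for k in k_grid:
        model = SpectralClustering(
            n_clusters=k,
            affinity="nearest_neighbors",
            n_neighbors=n_neighbors,
            assign_labels="kmeans",
            random_state=seed,
        )
        lab = model.fit_predict(scores)
        labels[k] = lab
        sil[k] = float(silhouette_score(scores, lab)) if len(np.unique(lab)) > 1 else -1.0
    chosen = max(k_grid, key=lambda k: sil[k])
    return ClusterResult(labels=labels[chosen], chosen_k=chosen, silhouettes=sil)


def cluster_profiles(
    features: pd.DataFrame,
    k_grid=DEFAULT_K_GRID,
    seed: int = 0,
    embed_seed: int | None = None,
) -> ClusterResult:
    """Convenience: PCA(>95%) -> spectral clustering (silhouette k) -> UMAP."""
    scores, d95 = reduce_pca_95(features)
    res = cluster_with_silhouette(scores, k_grid=k_grid, seed=seed)
    res.d95 = d95
    res.index = features.index if isinstance(features, pd.DataFrame) else None
    if scores.shape[0] >= 4:
        res.embedding = embed_2d(scores, seed=seed if embed_seed is None else embed_seed)
    return res


# ---------------------------------------------------------------------------
# Binomial-logit GLMM (lme4 backend)
# ---------------------------------------------------------------------------


@dataclass
class GlmmResult:
    """Fixed effects (log-odds), random-effect variances, Tukey contrasts."""

    fixed_effects: pd.DataFrame  # term, estimate, se, z, p
    random_variances: dict[str, float]
    contrasts: pd.DataFrame | None  # contrast, estimate, se, z, p_tukey
    converged: bool
    separation: bool = False
    messages: list[str] = field(default_factory=list)


def _rscript() -> str:
    path = shutil.which("Rscript")
    if path is None:  # pragma: no cover - environment guard
        raise RuntimeError("Rscript not found on PATH; the GLMM backend requires R with lme4")
    return path


def _run_r(script: str, workdir: Path) -> dict:
    script_path = workdir / "fit.R"
    script_path.write_text(script)
    proc = subprocess.run(
        [_rscript(), "--vanilla", str(script_path)],
        capture_output=True, text=True, cwd=workdir,
    )
    out_path = workdir / "result.json"
    if proc.returncode != 0 or not out_path.exists():
        raise RuntimeError(f"lme4 fit failed:\n{proc.stderr[-2000:]}")
    return json.loads(out_path.read_text())


def _check_separation(df: pd.DataFrame, response: str, trials: int, fixed: list[str]) -> bool:
    for term in fixed:
        agg = df.groupby(term)[response]
        if (agg.max() == 0).any() or (agg.min() == trials).any():
            return True
    return False


_R_PREAMBLE = """suppressMessages({library(lme4); library(multcomp); library(jsonlite)})
d <- read.csv("data.csv")
"""


def fit_group_glmm(
    data: pd.DataFrame,
    response: str = "fs_count",
    trials: int = 6,
    fixed: list[str] | None = None,
    random: list[str] | None = None,
    tukey: bool = True,
) -> GlmmResult:
    """Fit FS counts out of ``trials`` with a binomial-logit mixed model.

    ``fixed`` columns become factors (e.g. cluster id, familiarisation);
    ``random`` columns become independent random intercepts (group identity,
    trial number, experimental group).  Complete separation (a fixed-effect
    level with all-0 or all-``trials`` responses) and non-convergence are
    flagged on the result, never silently dropped.
    """
    fixed = fixed or ["cluster"]
    random = random or ["group"]
    for col in [response, *fixed, *random]:
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    if data[response].min() < 0 or data[response].max() > trials:
        raise ValueError(f"{response} must lie in 0..{trials}")
    for term in fixed:
        if data[term].nunique() < 2:
            raise ValueError(f"fixed effect {term!r} needs >= 2 levels")

    separation = _check_separation(data, response, trials, fixed)
    if data[response].nunique() == 1:
        # fully degenerate response: a fit is meaningless
        return GlmmResult(
            fixed_effects=pd.DataFrame(columns=["term", "estimate", "se", "z", "p"]),
            random_variances={}, contrasts=None, converged=False, separation=True,
            messages=["response is constant: complete separation"],
        )

    fix_part = " + ".join(fixed)
    ran_part = " + ".join(f"(1|{r})" for r in random)
    factor_lines = "\n".join(f'd${t} <- factor(d${t})' for t in [*fixed, *random])
    tukey_block = ""
    if tukey:
        tukey_block = f"""
gl <- tryCatch(summary(glht(fit, linfct = mcp({fixed[0]} = "Tukey"))), error = function(e) NULL)
if (!is.null(gl)) {{
  out$contrasts <- data.frame(
    contrast = names(gl$test$coefficients),
    estimate = as.numeric(gl$test$coefficients),
    se = as.numeric(gl$test$sigma),
    z = as.numeric(gl$test$tstat),
    p_tukey = as.numeric(gl$test$pvalues))
}}
"""
    script = f"""{_R_PREAMBLE}
{factor_lines}
fit <- glmer(cbind({response}, {trials} - {response}) ~ {fix_part} + {ran_part},
             family = binomial, data = d)
msgs <- unlist(fit@optinfo$conv$lme4$messages)
fe <- summary(fit)$coefficients
vc <- as.data.frame(VarCorr(fit))
out <- list(
  fixed = data.frame(term = rownames(fe), estimate = fe[,1], se = fe[,2],
                     z = fe[,3], p = fe[,4]),
  random = setNames(as.list(vc$vcov), vc$grp),
  messages = if (is.null(msgs)) character(0) else msgs)
{tukey_block}
write(toJSON(out, digits = 10, na = "null"), "result.json")
"""
    with tempfile.TemporaryDirectory() as tmp:
        workdir = Path(tmp)
        data.to_csv(workdir / "data.csv", index=False)
        res = _run_r(script, workdir)
    messages = list(res.get("messages", []))
    contrasts = None
    if res.get("contrasts"):
        contrasts = pd.DataFrame(res["contrasts"]).filter(regex=r"^[^_]")
    return GlmmResult(
        fixed_effects=pd.DataFrame(res["fixed"]).filter(regex=r"^[^_]"),
        random_variances={k: float(v[0] if isinstance(v, list) else v)
                          for k, v in res.get("random", {}).items()},
        contrasts=contrasts,
        converged=not any("fail" in m.lower() for m in messages),
        separation=separation,
        messages=messages,
    )


def fit_group_glmm_batch(
    data: pd.DataFrame,
    response: str = "fs_count",
    trials: int = 6,
    fixed_term: str = "condition",
    random_term: str = "group",
    replicate_col: str = "replicate",
) -> pd.DataFrame:
    """Fit one two-level binomial GLMM per replicate in a single R session.

    Returns a frame (replicate, estimate, se, ci_lo, ci_hi, converged) for
    the non-reference level of ``fixed_term``; the 95% CI is Wald.  Used by
    parameter-recovery simulations, where spawning one R process per fit
    would dominate the runtime.
    """
    for col in [response, fixed_term, random_term, replicate_col]:
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    script = f"""{_R_PREAMBLE}
d${fixed_term} <- factor(d${fixed_term})
d${random_term} <- factor(d${random_term})
reps <- sort(unique(d${replicate_col}))
rows <- lapply(reps, function(r) {{
  di <- d[d${replicate_col} == r, ]
  fit <- tryCatch(
    glmer(cbind({response}, {trials} - {response}) ~ {fixed_term} + (1|{random_term}),
          family = binomial, data = di),
    error = function(e) NULL)
  if (is.null(fit)) return(data.frame(replicate = r, estimate = NA, se = NA,
                                      ci_lo = NA, ci_hi = NA, converged = FALSE))
  fe <- summary(fit)$coefficients
  est <- fe[2, 1]; se <- fe[2, 2]
  msgs <- unlist(fit@optinfo$conv$lme4$messages)
  data.frame(replicate = r, estimate = est, se = se,
             ci_lo = est - 1.959963984540054 * se, ci_hi = est + 1.959963984540054 * se,
             converged = is.null(msgs) || !any(grepl("fail", tolower(msgs))))
}})
write(toJSON(do.call(rbind, rows), digits = 10, na = "null"), "result.json")
"""
    with tempfile.TemporaryDirectory() as tmp:
        workdir = Path(tmp)
        data.to_csv(workdir / "data.csv", index=False)
        res = _run_r(script, workdir)
    return pd.DataFrame(res)
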
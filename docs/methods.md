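# Methods

This note documents the models and procedures implemented in `loomsync`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the package's known limitations.

## Behavioural states from speed

Speeds are computed at 5 fps from calibrated (cm) coordinates as
frame-to-frame Euclidean displacement × fps, then smoothed with a
**trailing** moving average of window 5.  Two edge conventions are explicit
choices (upstream tools rarely document theirs): the first frame's speed
duplicates frame 1's, and the leading `window − 1` frames average over the
frames available so far.  Both preserve the exact 50/50/50 frame split of
the before/during/after intervals and affect at most a handful of frames.

Frame typing uses two speed thresholds: freezing-like strictly below
`v_freeze` = 0.2 cm/s, high-speed at or above `v_high` = 6 cm/s, normal in
between.  Interval classification (per 10-s, 50-frame interval):

* **HS** if high-speed frames total ≥ `hs_min_s` = 0.2 s (one frame) — a
  detection rule for rapid escape bursts;
* otherwise **FS** if freezing-like frames total ≥ `fs_min_s` = 8 s;
* otherwise **NS**.

Two ambiguities in the state definitions are resolved as follows and kept
configurable on `ThresholdSpec`:

* "persisted ≥ 8 s" is read as **total** freezing duration within the
  interval, not the longest consecutive run (`freeze_duration=
  "consecutive"` switches); the companion "< 2 s" NS rule reads most
  naturally as a total.
* When HS and FS criteria co-occur (a burst inside an otherwise frozen
  interval), **HS wins** (`precedence=("HS", "FS", "NS")`): one frame at
  ≥ 6 cm/s is the defined trigger of an escape event.
* Intervals with 2–8 s of total freezing and no high frame are NS, making
  the three-state space exhaustive — required for the 27-pattern analysis.

`derive_thresholds` re-derives both thresholds from a velocity matrix the
way they were originally motivated: `v_freeze` is the KDE minimum between
the two largest modes of the post-LS speed density (freezing vs swimming);
`v_high` is the smallest speed above the pre-LS **swimming** peak at which
the density falls below 1% of that peak.  Numerical choices: Gaussian KDE
with a fixed 0.05 cm/s bandwidth (narrow enough to resolve the sub-0.2
freezing mode; Scott's rule over-smooths it), a 2048-point grid, a
bimodality guard (the trough must dip below 50% of the smaller mode), and
the swimming peak constrained above the derived freezing trough so a tall
freezing mode in the pre-LS data cannot masquerade as the reference peak.
Every failure path falls back to (0.2, 6.0) with a warning, never silently.

## Transition statistics

Triples (before, during, after) ∈ {FS, NS, HS}³ index 27 patterns
(FS=0, NS=1, HS=2; index = 9·b + 3·d + a).  One-step transition matrices
count transitions and row-normalise; rows with no observations are left
all-zero and flagged rather than divided.  Enrichment per pattern is the
exact binomial upper tail P(X ≥ k), X ~ Bin(n, 1/27), i.e. a one-sided
test for *over*-representation, with Benjamini–Hochberg FDR across the
full 27-pattern family (zero-count patterns stay in the family with p = 1;
they cannot create false positives and keep the family fixed).  The
27-dimensional representation retains structural zeros throughout.

## Group-synchrony test

For each trial the FS count (0–6) is tallied.  The null of independent
responding is materialised by seeded shuffles: within each trial index the
FS indicators of all individuals are pooled across groups, permuted, and
reassigned to groups of six (1000 replicates, seeds 1…1000); a `global`
pooling mode exists because the within-trial-index reading of the
procedure, while more faithful to the trial structure, is not the only
one.  The observed 7-bin histogram is compared with the replicate-averaged
null proportions by χ² with expected counts `E_b = p̄_b × n_trials` and
df = 6 (plug-in expectation, bins merged only if an expectation is zero).
Only the binary after-LS FS indicator is shuffled — it is the only input
the test statistic consumes.

**Calibration caveat.**  Because the shuffle preserves the data's own
margins, the expected counts are estimated from the same data being
tested, and the df = 6 framing overcounts slightly: under a true
independence null the measured type-I rate at α = 0.05 is ≈ 2.5–3.5%
rather than 5% (mildly conservative).  Power in the consensus regime is
unaffected in practice (rejection probability ≈ 1 at α = 0.001 for the
17 × 10 design).  The plug-in/df = 6 formulation is retained because it is
the convention this analysis follows; the replicate-level histograms are
kept on the `NullDistribution` for anyone wanting a fully permutation-based
p-value.

## Group profiles

Per-group features are the relative frequencies of the 27 patterns over
the group's 60 individual-trials.  PCA retains the smallest d95 dimensions
exceeding 95% cumulative explained variance.  Spectral clustering runs on
the PCA scores over k = 2…6 with a symmetrised nearest-neighbour affinity
using ~√n neighbours — with a few dozen groups, sklearn's default of 10
neighbours wires every point across cluster boundaries — and the k with
the highest silhouette (computed in the same score space) is selected.
The 2-D UMAP embedding (seeded, default neighbourhood 15 capped at n − 1,
min_dist 0.1) is for visualisation only; clustering in the
higher-fidelity PCA space is the conservative reading of the original
pipeline, and a caller can cluster the embedding instead by passing it as
the score matrix.

FS counts per group-trial (successes out of 6) are modelled with a
binomial-logit GLMM — fixed effects for cluster and/or familiarisation,
independent random intercepts for group identity, trial number, and
experimental group — fitted by maximum likelihood in lme4 through
`Rscript`, with Tukey-adjusted pairwise contrasts from multcomp.  This is
the same toolchain the field uses for hierarchical count data; the Python
surface pre-checks complete separation (any fixed-effect level all-0 or
all-6) and flags it, returns lme4's convergence messages verbatim, and a
batch mode fits many replicates in one R session (one process per fit
would dominate simulation runtimes).

## The synthetic-data generator

The generator exists because raw data for this assay are typically not
deposited; it is a first-class, tested module, and its defaults are the
study design: 17 groups (familiar) or 12 (unfamiliar) of 6 fish, 10
trials, 5 fps, a 20.25 × 14.5 cm arena (midpoint of the stated 20.0–20.5
cm inner length).

**Speed dynamics.**  Freezing is near-immobile jitter capped at
`v_freeze_max` = 0.05 cm/s.  Normal swimming is an AR(1) log-speed process
(ρ = 0.9) with median 1.2 cm/s and stationary sd 1.0 cm/s, clipped to
(0.22, 5.8) cm/s; the persistence and spread are set so that the
*smoothed* pre-LS speed density keeps a tail whose 1%-of-peak point lies
near 6 cm/s and the post-LS density has its trough near 0.2 cm/s — i.e.
the generator reproduces the density structure from which the thresholds
were originally derived, so `derive_thresholds` recovers ≈ (0.2, 6) from
simulated data.  Escape bursts are 3 consecutive frames at `v_burst` = 12
cm/s, headed toward the arena centre (so wall reflections cannot fold the
displacement), because HS must survive window-5 smoothing: 3 × 12 cm/s
smooths to ≥ 7.2 cm/s, whereas a single 8 cm/s frame smooths to ~2.6 cm/s
and would make HS-intended intervals unrecoverable.  Boundaries reflect.

**Group behaviour.**  Each group draws an archetype — freeze-dominant,
non-freeze, or mixed — plus a Gaussian group-level logit offset
(sd 0.25).  Archetypes set the base log-odds of post-LS freezing
(+2.2 / −2.2 / −1.0), an escape-probability offset (+1.5 / −1.5 / 0
around a 0.4 base), a before-LS freezing rate (0.35 / 0.25 / 0.10 — the
extreme profiles' signature patterns include FS-before sequences, the
mixed profile's do not), and a **coupling scale** (1 / 1 / 0): the mixed
profile shows no all-or-none synchrony, so it is uncoupled.  Post-LS
freezing is a two-stage draw: independent intents at the base logit, then
a re-draw with the logit shifted by `coupling × (2·intent fraction − 1)`
(experiment default 3.0; 0 gives exact independence; ∞ forces the
majority intent on everyone regardless of archetype scale).  Escaping
individuals get a `logit(p_freeze_after_escape)` = logit(0.7) bonus,
reproducing the escape-then-freeze contingency.  The group-level logit sd
is set at 0.25 so within-archetype profile scatter stays below
between-archetype separation — the regime in which the three planted
profiles are recoverable by the clustering stage, mirroring the cleanly
separated group clusters this analysis is designed to detect.

**What it does not emulate:** hydrodynamics, body posture, wall-following
and thigmotaxis, inter-individual spatial interactions (cohesion,
alignment), the looming animation itself, tracking noise and identity
swaps.  Consequently, passing tests show that the *analysis stack* is
correct and well calibrated on data with the assumed statistical
structure; they cannot show that real fish satisfy that structure.  The
archetype/coupling mechanism is a stand-in for an unknown individual-level
trait model, not an inference about mechanism — whether familiarity acts
by raising social sensitivity or by homogenising traits is explicitly
unresolved, and this generator takes no position.

`simulate_states` is the state-level fast path used by the statistical
simulations (calibration, power, recovery — the downstream stages consume
states, not coordinates); `simulate_experiment` additionally synthesises
trajectories and is used wherever the I/O and classification stages are
under test.

## Problem sizes used by the test suite

Classifier/oracle agreement: 10,000 random 50-frame label sequences.
Enrichment calibration: 200 uniform-null replicates at n = 1020.
Shuffle-null accuracy: 400 Bernoulli(0.5) groups, 1000 replicates (the
shuffle conditions on the data's own prevalence, whose sampling error at
the 17-group size would exceed the 0.02 TV budget by itself; 400 groups
put it at ~0.006, 3σ ≈ 0.018).  Synchrony calibration: 500 simulated
independent experiments; power: 100 consensus experiments.  Cluster
recovery: one 17-group experiment with planted 6/6/5 archetypes.  GLMM
recovery: 100 replicates of a 17 + 12 group design with a true condition
log-odds difference of 2.0 and group-intercept sd 0.5.

## Known limitations

* The χ² synchrony test is mildly conservative (see above); with planted
  archetypes the silhouette occasionally (≈ 15% of seeds) prefers k = 2
  when the five mixed groups drift toward the non-freeze cloud — an
  intrinsic consequence of multinomial noise at 60 trials/group with a
  five-group cluster.
* With archetypes drawn from the default mixture weights (rather than
  planted), small mixed clusters (2–3 groups) are frequently absorbed, and
  chosen k = 2 is common — matching the instability one should expect of
  17-point clustering problems generally.
* The GLMM stage requires an R installation with lme4/multcomp/jsonlite;
  everything else is pure Python.
* `d95` on simulated data is typically 2–3, far below values reported for
  real datasets: the generator's three-archetype structure is intrinsically
  low-rank, real group profiles are not.
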
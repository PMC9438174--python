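# Methods

## Data model

All stages operate on `ExpressionDataset`: a finite log2 expression matrix
(transcripts × samples) of one kind (`gene` or `mirna`) with per-sample
`(day, replicate)` metadata. Samples are ordered by `(day, replicate)` at
load; rows with missing values are rejected (or dropped with an explicit
flag) because every downstream statistic assumes complete day grids.
Trajectory-level operations consume `TimeProfile` objects — per-transcript
day-mean log2 curves, where each day's value is the arithmetic mean over
that day's replicates. Correlation and fold-change statistics are computed
on these day means (n = number of days, 7 in the default design), matching
the day-level curves the selection rules are defined on; a
replicate-expanded correlation mode exists for sensitivity analysis but is
not the default, since it inflates n with replicate pseudo-replication.

Quantile normalization maps each within-column rank to the across-column
mean of the values at that rank; within-column ties receive the mean of the
tied ranks' means. Note a structural subtlety: with ties present, the
tie-averaging convention necessarily makes the tied column's value multiset
differ slightly from the other columns', so exact idempotency holds only for
tie-free (continuous) data.

## Filters

**Detection.** A transcript is "expressed" at a day when its day-mean
exceeds `detect_thr`; it survives when expressed at ≥ `min_timepoints`
(default 6) distinct days. The detection floor defaults to the 10th
percentile of the whole matrix — deterministic and data-adaptive, suitable
for log2 array intensities where the low tail is background.

**Segmental fold change.** The course is split into named phases
(`SegmentScheme`). Default ratio definition: linear fold change between the
phase's first and last sampled days, computed on day means and
exponentiated from log2 (`endpoints` strategy); a
`segment-mean-vs-day0` alternative compares the phase's mean level with the
transcript's earliest value. Thresholds 0.8/1.2 are inclusive. The filter
is a pure ratio rule — no replicate-level test statistic and therefore no
multiplicity correction — and the per-phase informative sets are unioned
downstream (their exact Venn partition is available via `segment_overlap`).

**Exponential trajectory.** Day-mean curves are fit with the two-term
exponential *y(t′) = a·e^{b t′} + c·e^{d t′}*, with days rescaled to
t′ ∈ [0, 1] for conditioning (this also makes the goodness invariant under
affine relabeling of the day axis). Fitting uses variable projection:
the rates (b, d) are optimized by bounded nonlinear least squares
(|rate| ≤ 25 on the unit interval) from 8 deterministic initializations
spanning growth/decay/mixed shapes, with the amplitudes (a, c) profiled out
by linear least squares at every step — no randomness, so no seed is
needed. The best converged start (lowest SSE) is reported; if no start
converges the transcript fails with flagged coefficients. Goodness is the
Pearson correlation R between fitted and observed values (threshold 0.7,
inclusive); a `sqrt_r2` option scores √max(R²,0) instead, since published
"R ≥ 0.7" conventions are ambiguous between the two.

*Known limitation:* a four-parameter exponential family evaluated at seven
day means has substantial capacity, so very rough (noise-like) profiles can
still reach R ≥ 0.7 — the filter's specificity against white noise is
limited by the model class itself (the global least-squares fit to i.i.d.
noise at n = 7 exceeds R = 0.7 in roughly half of draws). In practice the
filter follows the segmental stage, which has already removed most flat
transcripts on an independent criterion; the planted-recovery results below
should be read with that composition in mind.

## Interactions and iFC ranking

Validated miRNA→gene interactions are consumed from a flat TSV
(miRTarBase-style export) with ordinal confidence classes
`low < moderate < high < very_high`; duplicates on (miRNA, gene, source)
collapse to the highest confidence. Restriction keeps pairs whose both
endpoints survived the expression filters at ≥ `min_confidence` (default
`high`). The bipartite network is exported as GraphML with node fold
changes/regulation and edge confidence.

Pair scoring uses the sample Pearson correlation of the two day-mean
trajectories aligned on their shared day grid, with the exact two-sided
t-transform p-value. Sign rule: r < 0 marks an inverse pair; the
high-stringency signature requires strictly r < −0.5 (and p < `p_cut`,
default 1.0, i.e. correlation-only, since the published rule is a pure
correlation threshold; a Benjamini–Hochberg-adjusted column is emitted
alongside for users who want error control). Profiles are assigned from
the OLS slope of each trajectory against day: gene up & miRNA down →
Profile 1; the mirror → Profile 2. Ranking is ascending in r with
lexicographic (gene, miRNA) tie-break so output files are deterministic.
Kendall's τ is available as an exploratory alternative statistic; selection
follows Pearson.

## Cross-dataset concordance and grouping diagnostics

Each dataset contributes one direction per transcript: the sign of the
log2 change between its own day 0 and its own maximum sampled day (its
"most mature" sample); |Δ| < 1e−9 counts as flat. A transcript's support is
the percentage of external datasets agreeing with the reference direction,
over the datasets that actually cover the transcript (case-insensitive
symbol match); flat directions never count as agreement. Pass threshold:
≥ 50%. No ortholog mapping or cross-dataset normalization is attempted —
externals are assumed to arrive as comparable log2 matrices.

Grouping diagnostics summarize a transcript subset's ability to separate
samples by day: PCA scores (≤ 3 components), a Euclidean average-linkage
dendrogram emitted as Newick text (file-diffable), and the silhouette
coefficient of samples labelled by day as a scalar separation measure.

## Random-forest stage evaluation

For a transcript subset, a random forest (default 500 trees; the evaluation
scripts and tests use 100 for speed) classifies samples into differentiation
days under stratified k-fold cross-validation (default tenfold; folds are
reduced to the rarest class size with a warning when days have few
replicates). Out-of-fold class probabilities are pooled and summarized as a
macro-averaged one-vs-rest ROC AUC; micro-averaging was rejected because it
would let well-sampled days dominate a deliberately class-balanced design.
`n_observations` records samples × transcripts for funnel bookkeeping.
With a fixed seed the evaluation is bit-reproducible.

## Synthetic data generator

The generator emulates a replicated array time course in the in-house
design: days 0, 2, 4, 6, 8, 15, 30 with 3 replicates.

- **Background transcripts**: baseline ~ U[4, 12] log2 (typical array
  intensity spread) plus i.i.d. Gaussian noise (σ = 0.2 log2 units by
  default, homoscedastic — conventional for array log intensities).
- **Planted pairs**: each shares a latent monotone trajectory f(t) scaled
  to the pair's amplitude (default 3 log2 units ≈ 8-fold, a strongly
  time-regulated transcript). Shapes: `exp2`, a saturating a(1−e^{−3s})
  that also passes the exponential filter; `linear` and `sigmoid` exist to
  probe filter specificity. Profile 1 plants gene = base + f + ε and
  miRNA = base − f + ε; Profile 2 is mirrored. Planted baselines are drawn
  from U[8.5, 11] — the upper half of the intensity range — so the declining
  member of a mirrored pair stays above the detection floor for the whole
  course, as any transcript selectable by the cascade must.
- **Interaction table**: the true pairs at their stated confidence plus
  `decoy_edges` unique random background gene–miRNA edges with confidences
  uniform over the four classes.
- Everything is a deterministic function of the config seed; fixtures are
  written with SHA-256 manifests.

What the generator does **not** emulate: probe-level effects, batch or
platform effects, count-based (RNA-seq) noise, heteroscedasticity,
correlated background structure, or regulatory many-to-many topology
(each planted trajectory belongs to exactly one pair). Passing tests on
this fixture therefore demonstrate the cascade's statistical behavior under
clean planted signal, not robustness to real-data artifacts.

The canonical fixture (10 planted pairs — 8 Profile 1, 2 Profile 2,
alternating high/very-high confidence — 500 background genes, 200
background miRNAs, 500 decoys, σ = 0.2, seed 42) is the repository's
reference experiment: the full cascade recovers all 10 planted pairs in the
high-stringency set with one decoy admitted (precision 0.91) in ~10 s.

## Evaluation problem sizes

The test-suite and acceptance evaluations use deliberately desk-scale
settings: 100-tree forests with 3-fold CV on the 21-sample canonical design
for stage comparisons, and, for the permutation-null calibration of the AUC
(labels shuffled), a 7-day × 12-replicate background design — 84 samples
give the null distribution enough samples per class to concentrate near
0.5, which a 21-sample design cannot (its null AUC has sd ≈ 0.10 purely
from sampling noise).

## Pipeline orchestration

`run_cascade` composes the stages in memory; `run_all` drives it from a
YAML config, writes per-stage TSVs, the ranked-pair table, the GraphML
network and a JSON run report whose funnel counts are non-increasing along
the cascade per transcript kind. Stage failures abort with the stage name;
partial outputs are retained beside a `.partial` marker. The segmental
stage can be skipped by config flag (the exponential filter then applies to
all detected transcripts). All randomness funnels through a single config
seed. A thin click CLI exposes each stage plus the full run; stages compose
via intermediate TSVs.
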
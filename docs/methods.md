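# Methods

This note documents the statistical models, conventions and design choices
behind `checkmine`, in the order the pipeline runs them.

## Data model and file conventions

Expression matrices are genes × samples on the log2 scale (log2-normalised
RSEM for RNA-seq, median-collapsed probe intensities for microarray), read
and written as tab-separated UTF-8 text with `NA` as the missing token.
Duplicate gene symbols are collapsed to the per-sample median — the same
convention as microarray probe collapsing — applied uniformly to all
platforms. Missing entries stay missing (NaN) end to end; correlations use
pairwise-complete observations and never impute. Sample identifiers must be
unique within a matrix; matrices from different platforms are separate
objects and are never merged.

All randomness flows through `numpy` generator streams derived from one run
seed plus a stage label (hashed with crc32), so results are bit-reproducible
and per-seed-gene searches are independent of the order in which they run.

## Evolutionary correlation search

The search space for one seed gene is the set of all other genes; an
individual is a single candidate gene. Fitness is R² between candidate and
seed computed on a fresh random subsample of ceil(f·n) observations
(default f = 0.8), redrawn per evaluation, which makes fitness a noisy but
unbiased surrogate of the full-data R². Each generation applies
tournament selection (k = 3), elitism (2), mutation that jumps a fraction
(0.3) of offspring to uniformly drawn not-yet-evaluated genes, and the
injection of 5 random immigrants from the unevaluated pool. Ties in
selection break by gene index, so a fixed seed reproduces the search
exactly.

Immigrants are drawn without replacement from the unevaluated pool, so
coverage (the fraction of candidates scored at least once; the seed itself
is excluded from the denominator) grows by at least the immigrant count per
generation and the search terminates at 100% coverage by construction. At
termination every gene is re-scored on the **full** data and the exported
feature list is exactly `{g : R² > 0.25}`, sorted by descending R². Two
consequences are deliberate: the export is deterministic given the data
(the GA affects only evaluation order), and an exhaustive full-data scan is
a built-in oracle (`exhaustive=True` / `--exhaustive`) the test suite uses
to verify set-identity under arbitrary GA configurations. Population size,
operators and the subsample fraction are artifact defaults — chosen for a
search that visibly explores rather than sweeps — because no external
source fixes them; the R² > 0.25 export filter and the 100%-coverage
termination rule are the fixed, load-bearing conventions. Zero-variance
vectors get r = 0 with a degeneracy flag; fewer than 30 pairwise-complete
observations is an error naming both genes.

## Intersections

Feature lists from the nine-seed panel are combined into a boolean
gene × seed membership matrix. The common-gene report keeps genes present
in ≥ m of K lists (default 6 of 9) and ranks by overlap count, then by the
gene's maximum R² across lists, then by symbol — the tie rules are the
artifact's own, fixed for determinism. Exclusive membership patterns (the
UpSet decomposition) partition the genes, so pattern counts always sum to
the number of distinct genes; the package exports plot-ready tables rather
than rendering plots. When two platforms are analysed, the ≥ m filter is
applied per platform and the reports are then intersected, preserving the
first report's ranking.

## Synthetic bulk cohort

Expression is multivariate normal on the log2 scale. The planted common
correlate is the latent factor f; each linked seed is
a·f + √(1−a²)·ε with a equal to the target correlation (default 0.75
against 6 of the 9 seeds), which makes the target correlation exact in
population and the construction positive semi-definite for any |a| ≤ 1
(a = 1 with zero noise gives exact collinearity). Linked seeds are mutually
correlated at a², matching the empirical fact that checkpoint genes
co-express. Background genes come in equicorrelated blocks (default size
10, r = 0.3), low enough that no background gene passes the R² > 0.25
filter in expectation; the leading background genes carry the default
microenvironment marker symbols so the context stage runs on simulated
data. Gene means are uniform on [4, 12] and scales 1.5 on the log2 scale —
typical magnitudes for log2 expression data.

Disease-free survival is exponential with baseline hazard ln2/36 per month
(median DFS 36 months) multiplied by the spec hazard ratio (default 2) for
samples above the nearest-rank cutpoint quantile (default 0.43) of the
planted gene's expression. Censoring is independent exponential with its
rate set so the expected censored fraction approximates the spec censor
rate (default 0.2). This is the simplest model under which the log-rank
scan and the proportional-hazards stage have known truth. Covariates (age,
sex, stage, MSI status) are irrelevant noise by construction; a
configurable fraction of covariate cells (default 0.1) is set missing.

The generator emulates structure, not the source cohorts' numbers: real
expression is heavier-tailed and more block-structured, hazards are not
exactly proportional, and censoring is administrative rather than
exponential. Passing tests therefore demonstrate that the pipeline recovers
planted truth under its own assumptions, not that any specific biological
finding is correct.

## Synthetic single-cell matrix

Cells are allocated to types by largest remainder (default 363 cells across
T-cell, B-cell, epithelial, fibroblast, endothelial, macrophage). FPKM
values are zero-inflated log-normal (default dropout 0.6) and transformed
to log2(FPKM+1), so the positivity threshold ≥ 1 (equivalently FPKM ≥ 1)
sits inside the dropout mass. Target-gene positivity is Bernoulli per cell
with a per-type fraction (default 0.6 in T-cells, ≤ 0.05 elsewhere);
positive cells draw FPKM ≥ 1 and negative cells stay strictly below, so the
planted fractions are exact in expectation. Checkpoint genes have their
log2-scale location raised by the checkpoint shift (default 1.5) in
target-positive cells; with shift 0, positive and negative cells share one
distribution exactly, which is what the null-calibration tests rely on.
The murine-style checkpoint comparison (all CD8 T cells, n ≈ 1192) is
emulated by setting the proportions to a single T-cell type.

## Survival conventions

* DFS = 0 patients are excluded before any survival computation.
* Percentile rule: nearest rank — the threshold is the ceil(q·n/100)-th
  smallest value; samples strictly above are "high", ties at the threshold
  are "low". A fixed convention is required for bit-reproducibility; this
  one puts the reported 43rd-percentile split at 43% low / 57% high on
  tie-free data.
* The log-rank statistic is computed by explicit risk-set tabulation,
  vectorised over many splits of the same cohort at once; it matches
  lifelines to 1e-8 on random instances (property-tested).
* The optimal cutpoint scans percentiles 10–90 in steps of 1 and selects
  the minimum p, ties to the lower percentile. Degenerate splits (an empty
  group) are skipped with a warning. The scan-minimum p is optimistic; the
  optional permutation adjustment re-runs the scan on B permutations of the
  expression vector and reports (1 + #{min pᵦ ≤ min p}) / (B + 1), floored
  at the observed minimum p so the adjusted value can never undercut the
  nominal one.
* Missing-indicator encoding: numeric covariates are mean-imputed with an
  added 0/1 missingness column; categoricals are dummy-coded against the
  first observed level with missing rows at the reference plus the
  indicator. The imputation constants are the artifact's choice — the
  method is named in the literature without them. Row count is never
  changed; fully missing covariates are dropped with a warning.
* Cox stages: every design column is fitted alone; columns with univariate
  p < α (default 0.05) — plus any terms on a clinical-relevance allowlist —
  enter one joint fit. Fitting delegates to lifelines' `CoxPHFitter`; the
  contract tested here is parameter recovery and the selection rule, not
  the optimiser. An empty selection skips the joint stage explicitly.

## Context statistics

Microenvironment scores are the arithmetic mean log2 expression of each
population's present marker genes — a transparent re-implementation of
marker-based population scoring; the default panel is a shipped config and
should be replaced by published marker lists for real analyses. Signature
scores use the same mean-of-present-genes rule (the fraction of genes found
is reported); a per-sample score was chosen over aggregating per-gene
correlations. Both scores are linear in member-gene expression.

Group tests delegate to scipy (Welch t with Welch–Satterthwaite df, one-way
ANOVA, asymptotic Mann–Whitney with mid-rank tie correction and no
continuity correction, Pearson chi-squared without continuity correction,
warning on expected counts < 5). The exact small-sample Mann–Whitney path
(both groups ≤ 8) is a full label-permutation enumeration of the U
statistic, valid under ties. Per-checkpoint comparisons report
Benjamini–Hochberg adjusted p alongside raw p.

## Problem sizes and calibration checks

The automated checks run the search on 20 cohorts of 1,000 genes × 150
samples (full nine-seed panels, mixed planted structures), cutpoint
recovery on 50 cohorts of n = 320 with hazard ratio 2, null permutation
calibration on 50 cohorts with B = 200 permutations, and 2,000 null
replicates per statistical test — sizes at which the binomial error of each
measured rate is small against its acceptance band while the whole suite
runs in minutes on one CPU.

## Known limitations

* Pearson correlation only; the filter criterion is R² and no rank-based
  alternative is offered.
* Single-gene individuals: the search does not explore multi-gene
  chromosomes or interactions.
* The proportional-hazards and exponential-censoring assumptions of the
  generator are idealisations; cutpoint-recovery rates measured on it do
  not transfer quantitatively to real cohorts.
* The permutation adjustment corrects selection optimism of the scan but
  assumes exchangeability of expression across samples.
* Cross-platform reconciliation is by gene symbol, exact and
  case-sensitive; no alias resolution is attempted.
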
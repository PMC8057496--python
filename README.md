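# checkmine

Evolutionary correlation mining of immune-checkpoint co-expression in
tumour transcriptomes, with downstream cutpoint survival analysis and
immune-context statistics.

## The problem

Response to immune-checkpoint blockade in colorectal cancer is largely
confined to hypermutated (MSI-H/dMMR) tumours, and robust predictive
biomarkers beyond MSI status are lacking. One route to candidates is
*commonality*: mine a tumour expression cohort for genes co-expressed with a
panel of immune-checkpoint genes (PDL1, PDCD1, CTLA4, LAG3, TIM3, TIGIT,
ICOS, IDO1, BTLA), and nominate the gene that recurs across the most
checkpoint-specific lists — the archetypal finding being *IL2RB* (CD122), a
T-cell interleukin-2 receptor subunit. `checkmine` implements that discovery
pipeline as a tested, reusable library for anyone who wants to run, probe or
extend this style of analysis:

1. **Evolutionary correlation search** (`checkmine.ga`). For each seed gene
   a genetic algorithm evolves a population of candidate genes; fitness is
   the squared Pearson correlation R² with the seed, evaluated on random
   subsamples of the observations. Random immigrants guarantee that every
   candidate is eventually scored; the search runs to 100% coverage, then
   every gene is re-scored on the full data and the exported feature list is
   exactly `{g : R²(g, seed) > 0.25}`. At full coverage the result is
   provably identical to an exhaustive scan (a built-in `--exhaustive`
   oracle mode makes this checkable), so the GA controls the *order* of
   evaluation — useful for anytime behaviour — never the final set.
2. **List intersection** (`checkmine.intersect`). UpSet-style exclusive
   membership patterns across the nine per-seed lists; genes in ≥ m of K
   lists (default m = 6) are reported, ranked by overlap count, then maximum
   R², then symbol; reports from two platforms (microarray / RNA-seq) can be
   intersected.
3. **Survival analysis** (`checkmine.survival`). Disease-free-survival (DFS)
   filtering (DFS = 0 excluded), an optimal percentile cutpoint found by
   scanning percentiles 10–90 for the minimum two-group log-rank p (with a
   permutation adjustment for the min-p optimism), Kaplan–Meier curves, and
   univariate → multivariate Cox proportional hazards with missing-indicator
   covariate encoding.
4. **Immune context** (`checkmine.context`). Marker-mean microenvironment
   (MCP-style) population scores and their correlation with a gene;
   predictive-signature scores; single-cell positivity calls at
   log2(FPKM+1) ≥ 1; Mann–Whitney checkpoint comparisons between positive
   and negative cells; Welch t, ANOVA and chi-squared group tests.
5. **Synthetic cohorts** (`checkmine.simulate`). A generator that plants a
   known common correlate (target correlation with a chosen subset of
   seeds), a hazard step at a chosen expression percentile for DFS, clinical
   covariates with missingness, and single-cell matrices with cell-type
   structure — so every stage can be tested end-to-end against known truth.

## Core quantities

For seed *s* and candidate *g* with pairwise-complete observations
x, y over n samples:

    r = Σ(xᵢ−x̄)(yᵢ−ȳ) / √(Σ(xᵢ−x̄)² Σ(yᵢ−ȳ)²),   filter: R² = r² > 0.25

The two-group log-rank statistic sums over distinct event times t with d(t)
events, n(t) at risk and n₁(t) at risk in the high group:

    χ² = (O₁ − E₁)² / V,   E₁ = Σ d·n₁/n,
    V = Σ d·(n₁/n)(1 − n₁/n)(n − d)/(n − 1)

The optimal cutpoint is the percentile q ∈ [10, 90] minimising the log-rank
p of the split at the nearest-rank q-th percentile (ties at the threshold go
to the low group); the permutation-adjusted p is the fraction of expression
permutations whose minimum scanned p is at or below the observed minimum.

## Worked example

Simulate a 500-gene × 320-sample cohort in which IL2RB is planted at
r = 0.75 against 6 of the 9 checkpoint seeds and carries a hazard-ratio-2
DFS step at its 43rd expression percentile, then run the whole pipeline:

```
$ printf 'n_genes: 500\nn_samples: 320\n' > spec.yaml
$ checkmine all --spec spec.yaml --seed 42 --permutations 200 --out-dir demo
simulated cohort: 500 genes x 320 samples -> demo
PDL1: 6 genes pass R^2 > 0.25
PDCD1: 5 genes pass R^2 > 0.25
CTLA4: 5 genes pass R^2 > 0.25
LAG3: 6 genes pass R^2 > 0.25
TIM3: 6 genes pass R^2 > 0.25
TIGIT: 6 genes pass R^2 > 0.25
ICOS: 0 genes pass R^2 > 0.25
IDO1: 0 genes pass R^2 > 0.25
BTLA: 0 genes pass R^2 > 0.25
IL2RB: 6/9 lists (max R^2 = 0.585)
IL2RB: optimal percentile 43, log-rank p = 8.572e-06
IL2RB across cell types: F = 25.04, p = 1.22e-21
```

Reading the output: the six seeds linked to the planted gene each export a
short feature list (the planted gene plus the mutually correlated seeds);
the three unlinked seeds export empty lists. The intersection stage finds
exactly one gene in ≥ 6 of 9 lists — IL2RB, the planted correlate — with no
background false positives. The survival stage recovers the planted 43rd
percentile as the minimum-p split (`demo/survival/cutpoint.json` also holds
the log-rank χ² = 19.81 and the permutation-adjusted p ≈ 0.005), and the
single-cell stage confirms that IL2RB expression differs strongly across
cell types, driven by the T-cell compartment. Per-stage outputs (feature
lists, membership matrix, exclusive-pattern counts, KM tables, Cox term
tables, checkpoint positivity comparisons) are tab-separated files under
`demo/`.

Re-running the same command reproduces every output file byte for byte;
each stage is also available as its own subcommand (`simulate`, `explore`,
`intersect`, `survival`, `context`) and as plain library functions.

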
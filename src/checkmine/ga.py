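"""Evolutionary correlation search for genes co-expressed with a seed gene.

For one seed gene the search evolves a population of candidate genes.  Each
individual is a single candidate; its fitness is the squared Pearson
correlation (R^2) with the seed, evaluated on a fresh random subsample of the
observations.  Random immigrants guarantee that every candidate gene is
eventually evaluated; the search terminates at 100% coverage, at which point
every gene is re-scored on the full data and the exported feature list is
exactly the set of genes with full-data R^2 above the filter threshold.  The
evolutionary search therefore changes the *order* in which candidates are
examined — never the final filtered set, which coincides with an exhaustive
scan and is used as its own oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, Platform, derive_rng


class PearsonResult(NamedTuple):
    r: float
    r2: float
    degenerate: bool
    n_pairs: int


@dataclass
class GAConfig:
    """Tuning knobs for the evolutionary search.

    The filter ``r2_threshold`` (default 0.25) is the criterion applied to
    exported feature lists; the remaining parameters only shape the order of
    evaluation.
    """

    population_size: int = 50
    mutation_rate: float = 0.3
    tournament_k: int = 3
    elitism: int = 2
    subsample_fraction: float = 0.8
    immigrant_count: int = 5
    r2_threshold: float = 0.25
    min_pairwise_n: int = 30
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must lie in (0, 1]")
        if self.elitism >= self.population_size:
            raise ValueError("elitism must be smaller than population_size")
        if not 0 < self.r2_threshold < 1:
            raise ValueError("r2_threshold must lie in (0, 1)")
        if self.immigrant_count < 1:
            raise ValueError("immigrant_count must be >= 1")


class FeatureEntry(NamedTuple):
    gene: str
    r: float
    r2: float


@dataclass
class FeatureList:
    """Per-seed export: candidates whose full-data R^2 passed the filter."""

    seed_gene: str
    entries: list[FeatureEntry]
    platform: Platform = Platform.rnaseq
    coverage_at_export: float = 1.0

    def __post_init__(self) -> None:
        self.platform = Platform(self.platform)
        r2s = [e.r2 for e in self.entries]
        if any(x < y for x, y in zip(r2s, r2s[1:])):
            raise ValueError("entries must be sorted by descending r2")
        if any(e.gene == self.seed_gene for e in self.entries):
            raise ValueError("seed gene cannot appear in its own feature list")
        for e in self.entries:
            if abs(e.r2 - e.r * e.r) > 1e-12:
                raise ValueError(f"r2 inconsistent with r for {e.gene}")

    @property
    def genes(self) -> list[str]:
        return [e.gene for e in self.entries]

    def __eq__(self, other) -> bool:
        return (isinstance(other, FeatureList)
                and self.seed_gene == other.seed_gene
                and self.platform == other.platform
                and self.entries == other.entries)


@dataclass
class CoverageState:
    """Which candidate genes have been scored at least once.

    The denominator excludes the seed gene itself (its self-correlation is
    trivially 1), so coverage 1.0 means every *other* gene was evaluated.
    """

    n_candidates: int
    evaluated: set[str] = field(default_factory=set)

    @property
    def coverage(self) -> float:
        return len(self.evaluated) / self.n_candidates


def pearson_r2(
    x: np.ndarray,
    y: np.ndarray,
    min_pairwise_n: int = 30,
    x_name: str = "x",
    y_name: str = "y",
) -> PearsonResult:
    """Pearson product-moment r and R^2 on pairwise-complete observations.

    Zero-variance input yields r = 0, R^2 = 0 with the degenerate flag set;
    fewer than ``min_pairwise_n`` complete pairs raises, naming both genes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have the same length")
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < min_pairwise_n:
        raise ValueError(
            f"only {n} pairwise-complete observations between {x_name!r} and "
            f"{y_name!r} (minimum {min_pairwise_n})"
        )
    xv = x[ok]
    yv = y[ok]
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        return PearsonResult(0.0, 0.0, True, n)
    r = float(xc @ yc) / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    return PearsonResult(r, r * r, False, n)


def evaluate_fitness(
    matrix: ExpressionMatrix,
    seed_gene: str,
    candidate_gene: str,
    subsample_fraction: float,
    rng: np.random.Generator,
    coverage: CoverageState | None = None,
    min_pairwise_n: int = 30,
) -> float:
    """R^2 between seed and candidate on a fresh observation subsample.

    A subsample of ceil(fraction * n_samples) observations is drawn without
    replacement for every call, making fitness a noisy unbiased estimate of
    the full-data R^2.  The candidate is recorded into ``coverage``.
    """
    x = matrix.gene(seed_gene)
    y = matrix.gene(candidate_gene)
    n = x.shape[0]
    k = math.ceil(subsample_fraction * n)
    if k < n:
        idx = rng.choice(n, size=k, replace=False)
        x, y = x[idx], y[idx]
    res = pearson_r2(x, y, min_pairwise_n=min(min_pairwise_n, k),
                     x_name=seed_gene, y_name=candidate_gene)
    if coverage is not None:
        coverage.evaluated.add(candidate_gene)
    return res.r2


def _full_scan_stats(
    values: np.ndarray, seed_row: int, min_pairwise_n: int,
    gene_names: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pairwise-complete Pearson r of every gene against the seed.

    Returns (r, n_pairs) arrays over all genes (seed included, r=1 there).
    """
    s = values[seed_row]
    mask_s = ~np.isnan(s)
    mask_x = ~np.isnan(values)
    both = mask_x & mask_s
    n = both.sum(axis=1)
    sz = np.where(mask_s, s, 0.0)
    xz = np.where(mask_x, values, 0.0)
    sum_x = (xz * both).sum(axis=1)
    sum_y = both @ sz
    sum_xy = (xz * both) @ sz
    sum_xx = (xz * xz * both).sum(axis=1)
    sum_yy = both @ (sz * sz)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sum_xy - sum_x * sum_y / n
        vx = sum_xx - sum_x**2 / n
        vy = sum_yy - sum_y**2 / n
        r = cov / np.sqrt(vx * vy)
    r = np.where((vx <= 0) | (vy <= 0), 0.0, r)  # zero-variance convention
    np.clip(r, -1.0, 1.0, out=r)
    low = (n < min_pairwise_n) & (np.arange(len(n)) != seed_row)
    if low.any():
        bad = gene_names[int(np.flatnonzero(low)[0])]
        raise ValueError(
            f"fewer than {min_pairwise_n} pairwise-complete observations "
            f"between {gene_names[seed_row]!r} and {bad!r}"
        )
    return r, n


def exhaustive_scan(
    matrix: ExpressionMatrix,
    seed_gene: str,
    r2_threshold: float = 0.25,
    min_pairwise_n: int = 30,
) -> FeatureList:
    """Brute-force full-data correlation of every gene against the seed.

    The oracle mode: at 100% coverage the evolutionary search exports exactly
    this list.
    """
    if seed_gene not in matrix.values.index:
        raise KeyError(f"seed gene {seed_gene!r} not in matrix")
    genes = matrix.gene_ids
    seed_row = genes.index(seed_gene)
    r, _ = _full_scan_stats(matrix.values.to_numpy(dtype=float), seed_row,
                            min_pairwise_n, genes)
    r2 = r * r
    entries = [
        FeatureEntry(gene=genes[i], r=float(r[i]), r2=float(r2[i]))
        for i in range(len(genes))
        if i != seed_row and r2[i] > r2_threshold
    ]
    entries.sort(key=lambda e: (-e.r2, e.gene))
    return FeatureList(seed_gene=seed_gene, entries=entries,
                       platform=matrix.platform, coverage_at_export=1.0)


def run_ace_search(
    matrix: ExpressionMatrix,
    seed_gene: str,
    config: GAConfig | None = None,
    rng: np.random.Generator | None = None,
    trace: list | None = None,
) -> FeatureList:
    """Evolve candidate genes against one seed until 100% coverage.

    Generation loop: tournament selection on subsampled fitness, mutation
    jumps a fraction of offspring to not-yet-evaluated genes, elites are
    preserved, and ``immigrant_count`` unevaluated genes are injected each
    generation (guaranteeing coverage progress and hence termination).  When
    coverage reaches 1.0 every gene is re-scored with full-data R^2 and the
    filter is applied.  ``trace``, if given, collects
    (generation, coverage, best subsampled R^2) tuples.
    """
    config = config or GAConfig()
    if rng is None:
        rng = derive_rng(config.rng_seed, "ace", seed_gene)
    if seed_gene not in matrix.values.index:
        raise KeyError(f"seed gene {seed_gene!r} not in matrix")
    genes = matrix.gene_ids
    if len(genes) < 2:
        raise ValueError("matrix must contain at least 2 genes")

    values = matrix.values.to_numpy(dtype=float)
    seed_row = genes.index(seed_gene)
    candidates = np.array([i for i in range(len(genes)) if i != seed_row])
    state = CoverageState(n_candidates=len(candidates))
    evaluated_idx: set[int] = set()

    n_samples = values.shape[1]
    k_sub = math.ceil(config.subsample_fraction * n_samples)
    seed_vec = values[seed_row]
    has_nan = bool(np.isnan(values).any())
    min_n = min(config.min_pairwise_n, k_sub)

    def fitness(cand: int) -> float:
        if k_sub < n_samples:
            idx = rng.choice(n_samples, size=k_sub, replace=False)
        else:
            idx = slice(None)
        res = pearson_r2(seed_vec[idx], values[cand][idx],
                         min_pairwise_n=min_n,
                         x_name=seed_gene, y_name=genes[cand])
        evaluated_idx.add(cand)
        state.evaluated.add(genes[cand])
        return res.r2

    def draw_unevaluated(k: int) -> np.ndarray:
        pool = np.array([c for c in candidates if c not in evaluated_idx])
        if pool.size == 0:
            return np.array([], dtype=int)
        k = min(k, pool.size)
        return rng.choice(pool, size=k, replace=False)

    pop_size = min(config.population_size, candidates.size)
    population = rng.choice(candidates, size=pop_size, replace=False)

    generation = 0
    while True:
        fits = np.array([fitness(int(c)) for c in population])
        if trace is not None:
            trace.append((generation, state.coverage, float(fits.max())))
        if state.coverage >= 1.0:
            break

        # rank by (fitness desc, gene index asc) for deterministic ties
        order = np.lexsort((population, -fits))
        elites = population[order[: config.elitism]]

        n_offspring = pop_size - len(elites)
        offspring = np.empty(n_offspring, dtype=int)
        for j in range(n_offspring):
            contenders = rng.integers(0, pop_size, size=config.tournament_k)
            best = min(contenders,
                       key=lambda i: (-fits[i], population[i]))
            offspring[j] = population[best]

        mutate = rng.random(n_offspring) < config.mutation_rate
        n_mut = int(mutate.sum())
        if n_mut:
            jumps = draw_unevaluated(n_mut)
            offspring[np.flatnonzero(mutate)[: jumps.size]] = jumps

        immigrants = draw_unevaluated(min(config.immigrant_count, n_offspring))
        if immigrants.size:
            offspring[-immigrants.size:] = immigrants

        population = np.concatenate([elites, offspring])
        generation += 1

    r, _ = _full_scan_stats(values, seed_row, config.min_pairwise_n, genes)
    r2 = r * r
    entries = [
        FeatureEntry(gene=genes[i], r=float(r[i]), r2=float(r2[i]))
        for i in candidates
        if r2[i] > config.r2_threshold
    ]
    entries.sort(key=lambda e: (-e.r2, e.gene))
    return FeatureList(seed_gene=seed_gene, entries=entries,
                       platform=matrix.platform,
                       coverage_at_export=state.coverage)


def run_panel(
    matrix: ExpressionMatrix,
    seed_genes: Sequence[str],
    config: GAConfig | None = None,
    exhaustive: bool = False,
) -> list[FeatureList]:
    """One search per seed gene, on independent RNG streams.

    Streams are derived from (rng_seed, seed symbol) so per-seed results do
    not depend on panel order.  ``exhaustive=True`` swaps in the brute-force
    oracle scan.
    """
    config = config or GAConfig()
    absent = [g for g in seed_genes if g not in matrix.values.index]
    if absent:
        raise KeyError(f"seed genes absent from matrix: {absent}")
    out = []
    for seed in seed_genes:
        if exhaustive:
            out.append(exhaustive_scan(matrix, seed, config.r2_threshold,
                                       config.min_pairwise_n))
        else:
            rng = derive_rng(config.rng_seed, "ace", seed)
            out.append(run_ace_search(matrix, seed, config, rng=rng))
    return out
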
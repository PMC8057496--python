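"""Synthetic cohorts with the statistical structure the pipeline assumes.

The bulk generator plants a single-factor correlation structure: a "common
correlate" gene is linked at a target Pearson correlation to a chosen subset
of the nine immune-checkpoint seed genes, on top of block-correlated
background genes.  Disease-free survival is exponential with a hazard step at
a chosen percentile of the planted gene's expression, with independent
censoring, so the cutpoint-discovery and proportional-hazards stages have a
known truth.  The single-cell generator emulates log2(FPKM+1) matrices with
cell-type labels, zero-inflation, a controlled per-type positivity fraction
for a target gene, and a checkpoint-expression shift in target-positive
cells.  Structure is emulated, never the source datasets' numerical values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .context import CellProfileMatrix
from .io import CHECKPOINT_SEEDS, ClinicalTable, ExpressionMatrix, Platform


#: cell types mirroring a mixed tumour/microenvironment dissociation
DEFAULT_CELL_TYPES: dict[str, float] = {
    "T-cell": 0.25,
    "B-cell": 0.10,
    "epithelial": 0.35,
    "fibroblast": 0.12,
    "endothelial": 0.08,
    "macrophage": 0.10,
}

DEFAULT_SC_CHECKPOINTS = ("PDCD1", "PDL1", "LAG3", "CTLA4", "ICOS", "TIGIT")


@dataclass
class CohortSpec:
    """Parameters of the planted bulk cohort.

    Defaults mirror the emulated study conditions: nine checkpoint seeds, a
    planted common correlate linked to six of them at r = 0.75, a hazard step
    at the 43rd expression percentile, and ~20% independent censoring.
    """

    n_genes: int = 1000
    n_samples: int = 457
    seed_gene_names: tuple[str, ...] = CHECKPOINT_SEEDS
    planted_common_gene: str = "IL2RB"
    planted_r: float = 0.75
    n_seeds_linked: int = 6
    background_block_size: int = 10
    background_block_r: float = 0.3
    hazard_ratio: float = 2.0
    cutpoint_quantile: float = 0.43
    censor_rate: float = 0.2
    covariate_missing_rate: float = 0.1
    baseline_hazard: float = math.log(2) / 36.0  # median DFS ~36 months
    noise_scale: float = 1.0
    platform: Platform = Platform.rnaseq

    def __post_init__(self) -> None:
        if self.n_seeds_linked > len(self.seed_gene_names):
            raise ValueError("n_seeds_linked exceeds number of seed genes")
        if not abs(self.planted_r) <= 1:
            raise ValueError("planted_r must lie in [-1, 1]")
        for name, lo, hi in (("cutpoint_quantile", 0, 1),
                             ("censor_rate", 0, 1)):
            v = getattr(self, name)
            if not lo < v < hi:
                raise ValueError(f"{name} must lie in ({lo}, {hi})")
        if not 0 <= self.covariate_missing_rate <= 1:
            raise ValueError("covariate_missing_rate must lie in [0, 1]")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if self.n_genes < len(self.seed_gene_names) + 1:
            raise ValueError("n_genes too small for seeds + planted gene")


class CohortTruth(NamedTuple):
    """Ground truth of a simulated cohort, for test harnesses."""

    planted_gene: str
    linked_seeds: tuple[str, ...]
    cutpoint_quantile: float
    cutpoint_threshold: float
    high_group: tuple[str, ...]


def _planted_block_corr(spec: CohortSpec) -> np.ndarray:
    """Target correlation matrix of [seeds..., planted] under the
    single-factor construction (linked seeds load on the planted factor)."""
    k = len(spec.seed_gene_names)
    a = np.zeros(k + 1)
    a[:spec.n_seeds_linked] = spec.planted_r
    a[k] = 1.0
    corr = np.outer(a, a)
    np.fill_diagonal(corr, 1.0)
    return corr


def simulate_bulk_cohort(
    spec: CohortSpec, rng: np.random.Generator
) -> tuple[ExpressionMatrix, ClinicalTable, CohortTruth]:
    """Draw one bulk cohort: expression matrix, clinical table and truth.

    Expression is multivariate normal on the log2 scale.  The planted gene is
    the latent factor; each linked seed loads on it with coefficient
    ``planted_r`` so the target pairwise correlation is exact by
    construction.  Background genes come in blocks with equicorrelation
    ``background_block_r``.  Survival is exponential with the hazard
    multiplied by ``hazard_ratio`` for samples above the
    ``cutpoint_quantile`` of planted-gene expression.
    """
    corr = _planted_block_corr(spec)
    eig = np.linalg.eigvalsh(corr)
    if eig.min() < -1e-8:
        raise ValueError("infeasible correlation structure: target matrix "
                         "is not positive semi-definite")
    m = spec.background_block_size
    if m > 1 and spec.background_block_r < -1.0 / (m - 1):
        raise ValueError("infeasible background block correlation")

    k = len(spec.seed_gene_names)
    n = spec.n_samples
    sigma = spec.noise_scale

    # planted factor + seed loadings; unit-variance latent scale
    f = rng.standard_normal(n)
    a = np.zeros(k)
    a[:spec.n_seeds_linked] = spec.planted_r
    eps = rng.standard_normal((k, n))
    seeds_z = a[:, None] * f[None, :] + np.sqrt(1.0 - a**2)[:, None] * eps
    planted_z = f

    n_background = spec.n_genes - k - 1
    bg = np.empty((n_background, n))
    if n_background > 0:
        r_b = spec.background_block_r
        # equicorrelated block = shared factor + idiosyncratic noise
        done = 0
        while done < n_background:
            size = min(m, n_background - done)
            if size > 1 and r_b >= 0:
                g = rng.standard_normal(n)
                e = rng.standard_normal((size, n))
                bg[done:done + size] = (math.sqrt(r_b) * g
                                        + math.sqrt(1 - r_b) * e)
            else:
                bg[done:done + size] = rng.standard_normal((size, n))
            done += size

    z = np.vstack([seeds_z, planted_z[None, :], bg])
    # the leading background genes take the default microenvironment marker
    # symbols so MCP-style scoring runs out of the box on simulated cohorts
    from .context import DEFAULT_MARKER_PANEL

    marker_syms = [g for genes in DEFAULT_MARKER_PANEL.populations.values()
                   for g in genes]
    taken = set(spec.seed_gene_names) | {spec.planted_common_gene}
    marker_syms = [g for g in marker_syms if g not in taken][:n_background]
    bg_names = marker_syms + [f"BG{i:05d}"
                              for i in range(n_background - len(marker_syms))]
    gene_names = [*spec.seed_gene_names, spec.planted_common_gene, *bg_names]
    means = rng.uniform(4.0, 12.0, size=spec.n_genes)
    sds = np.full(spec.n_genes, 1.5) * sigma
    if sigma == 0.0:
        # degenerate-noise convention: keep the correlated signal, drop the
        # idiosyncratic scale jitter so linked genes are exactly collinear
        values = z + means[:, None]
    else:
        values = z * sds[:, None] + means[:, None]

    sample_ids = [f"S{i:04d}" for i in range(n)]
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_names, columns=sample_ids),
        platform=spec.platform,
    )

    # survival: hazard step at the planted gene's cutpoint quantile
    planted_expr = values[k]
    thr = float(np.sort(planted_expr)[
        max(0, math.ceil(spec.cutpoint_quantile * n) - 1)])
    high = planted_expr > thr
    lam = spec.baseline_hazard * np.where(high, spec.hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / lam)
    # exponential censoring tuned so P(censored) ~ censor_rate on average
    mu = spec.censor_rate / (1 - spec.censor_rate) * lam.mean()
    t_cens = rng.exponential(1.0 / mu, size=n)
    dfs = np.minimum(t_event, t_cens)
    event = t_event <= t_cens

    age = rng.normal(68.0, 10.0, size=n).round(1)
    sex = rng.choice(["M", "F"], size=n)
    stage = rng.choice(["II", "III"], size=n, p=[0.55, 0.45])
    msi = rng.choice(["MSI-H", "MSS"], size=n, p=[0.15, 0.85])
    clin = pd.DataFrame({
        "sample_id": sample_ids,
        "dfs_months": np.round(dfs, 4),
        "dfs_event": event,
        "msi_status": msi,
        "age": age,
        "sex": sex,
        "stage": stage,
    })
    for col in ("age", "sex", "stage"):
        miss = rng.random(n) < spec.covariate_missing_rate
        clin.loc[miss, col] = np.nan

    truth = CohortTruth(
        planted_gene=spec.planted_common_gene,
        linked_seeds=tuple(spec.seed_gene_names[:spec.n_seeds_linked]),
        cutpoint_quantile=spec.cutpoint_quantile,
        cutpoint_threshold=thr,
        high_group=tuple(np.array(sample_ids)[high]),
    )
    return expr, ClinicalTable(data=clin), truth


# ---------------------------------------------------------------------------
# Single-cell generator
# ---------------------------------------------------------------------------

@dataclass
class SingleCellSpec:
    """Parameters of the synthetic single-cell log2(FPKM+1) matrix."""

    n_cells: int = 363
    cell_type_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CELL_TYPES))
    target_gene: str = "IL2RB"
    target_gene_positive_fraction_by_type: Mapping[str, float] = field(
        default_factory=lambda: {"T-cell": 0.6, "B-cell": 0.05,
                                 "epithelial": 0.02, "fibroblast": 0.02,
                                 "endothelial": 0.02, "macrophage": 0.05})
    checkpoint_genes: tuple[str, ...] = DEFAULT_SC_CHECKPOINTS
    checkpoint_shift: float = 1.5
    n_background_genes: int = 50
    dropout_rate: float = 0.6
    positivity_threshold: float = 1.0

    def __post_init__(self) -> None:
        total = sum(self.cell_type_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("cell_type_proportions must sum to 1")
        for t, frac in self.target_gene_positive_fraction_by_type.items():
            if not 0 <= frac <= 1:
                raise ValueError(f"positive fraction for {t} out of [0, 1]")


def _allocate_cells(spec: SingleCellSpec) -> list[str]:
    """Largest-remainder allocation of n_cells across types."""
    types = list(spec.cell_type_proportions)
    raw = np.array([spec.cell_type_proportions[t] for t in types])
    counts = np.floor(raw * spec.n_cells).astype(int)
    rem = spec.n_cells - counts.sum()
    frac_order = np.argsort(-(raw * spec.n_cells - counts))
    for i in range(rem):
        counts[frac_order[i % len(types)]] += 1
    for t, c, p in zip(types, counts, raw):
        if p > 0 and c == 0:
            raise ValueError(
                f"cell type {t!r} requested with proportion {p} but "
                f"n_cells={spec.n_cells} allocates it zero cells")
    labels = []
    for t, c in zip(types, counts):
        labels.extend([t] * c)
    return labels


def simulate_single_cell(
    spec: SingleCellSpec, rng: np.random.Generator
) -> CellProfileMatrix:
    """Draw a synthetic single-cell log2(FPKM+1) matrix.

    FPKM values are zero-inflated log-normal; the transform log2(FPKM+1) is
    applied afterwards, so the >=1 positivity threshold (FPKM >= 1) sits
    inside the dropout mass.  Target-gene positivity per cell type follows
    the spec fractions exactly in expectation: positive cells draw FPKM >= 1,
    negative cells stay strictly below.  Checkpoint genes have their
    log2-scale location raised by ``checkpoint_shift`` in target-positive
    cells (a shift of zero means positive and negative cells share one
    distribution).
    """
    labels = _allocate_cells(spec)
    n = len(labels)
    cell_ids = [f"C{i:04d}" for i in range(n)]

    pos_frac = np.array([
        spec.target_gene_positive_fraction_by_type.get(t, 0.0)
        for t in labels
    ])
    positive = rng.random(n) < pos_frac

    genes = [spec.target_gene, *spec.checkpoint_genes,
             *(f"SCBG{i:03d}" for i in range(spec.n_background_genes))]
    fpkm = np.zeros((len(genes), n))

    # target gene: positives at FPKM >= 1, negatives strictly below 1
    fpkm[0] = np.where(
        positive,
        1.0 + rng.lognormal(mean=1.0, sigma=1.0, size=n),
        np.where(rng.random(n) < spec.dropout_rate, 0.0,
                 rng.uniform(0.0, 0.99, size=n)),
    )

    for j, _gene in enumerate(spec.checkpoint_genes, start=1):
        base = rng.normal(0.5, 1.0, size=n)
        shifted = base + spec.checkpoint_shift * positive
        expressed = rng.random(n) >= spec.dropout_rate
        fpkm[j] = np.where(expressed, 2.0 ** shifted, 0.0)

    for j in range(spec.n_background_genes):
        row = 1 + len(spec.checkpoint_genes) + j
        expressed = rng.random(n) >= spec.dropout_rate
        fpkm[row] = np.where(expressed,
                             rng.lognormal(mean=0.0, sigma=1.2, size=n), 0.0)

    values = np.log2(fpkm + 1.0)
    return CellProfileMatrix(
        values=pd.DataFrame(values, index=genes, columns=cell_ids),
        cell_types=pd.Series(labels, index=cell_ids, name="cell_type"),
        positivity_threshold=spec.positivity_threshold,
    )
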
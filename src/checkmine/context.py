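"""Microenvironment scoring, signature correlation and group statistics.

Covers the immune-context stages of the pipeline: transparent marker-mean
scoring of microenvironment cell populations (an MCP-style per-sample
abundance surrogate), per-sample predictive-signature scores, single-cell
positivity calls on the log2(FPKM+1) scale, checkpoint comparisons between
positivity classes, and the generic two-group / multi-group / categorical
tests used throughout.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ga import pearson_r2
from .io import ExpressionMatrix, SignatureDef

log = logging.getLogger("checkmine.context")


@dataclass
class CellProfileMatrix:
    """Single-cell log2(FPKM+1) matrix with per-cell type labels.

    Values are non-negative by construction of the transform; the positivity
    threshold (default 1.0, i.e. FPKM >= 1) is carried with the matrix.
    """

    values: pd.DataFrame  # genes x cells
    cell_types: pd.Series  # indexed by cell id
    positivity_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.positivity_threshold <= 0:
            raise ValueError("positivity threshold must be positive")
        arr = self.values.to_numpy(dtype=float)
        if np.nanmin(arr) < 0:
            raise ValueError("log2(FPKM+1) values must be non-negative")
        if list(self.values.columns) != list(self.cell_types.index):
            raise ValueError("cell_types index must match matrix columns")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class MarkerSetPanel:
    """Named marker-gene lists, one per microenvironment population."""

    populations: Mapping[str, Sequence[str]]

    def __post_init__(self) -> None:
        for name, genes in self.populations.items():
            if not list(genes):
                raise ValueError(f"population {name!r} has an empty gene list")


#: default panel shipped with the package; population names follow the
#: conventional immune/stromal compartments, marker symbols are synthetic
#: placeholders the cohort simulator knows how to populate — substitute
#: published marker lists for real data.
DEFAULT_MARKER_PANEL = MarkerSetPanel(populations={
    "T-cells": ["CD3D", "CD3E", "CD3G"],
    "Cytotoxic lymphocytes": ["GZMA", "PRF1", "CD8A"],
    "B-cells": ["CD19", "MS4A1", "CD79A"],
    "NK cells": ["NKG7", "KLRD1", "NCR1"],
    "Fibroblasts": ["COL1A1", "PDGFRB", "FAP"],
    "Endothelial cells": ["PECAM1", "VWF", "CDH5"],
})


def marker_set_score(
    matrix: ExpressionMatrix, panel: MarkerSetPanel
) -> pd.DataFrame:
    """Population x sample scores: mean log2 expression of present markers.

    Marker genes absent from the matrix are dropped with a warning; a
    population with no present genes is dropped entirely.
    """
    rows = {}
    for pop, genes in panel.populations.items():
        present = [g for g in genes if g in matrix.values.index]
        absent = [g for g in genes if g not in matrix.values.index]
        if absent:
            log.warning("population %s: markers absent from matrix: %s",
                        pop, absent)
        if not present:
            log.warning("population %s dropped: no marker genes present", pop)
            continue
        rows[pop] = matrix.values.loc[present].mean(axis=0)
    if not rows:
        raise ValueError("no panel population has any gene in the matrix")
    return pd.DataFrame(rows).T


def signature_score(
    matrix: ExpressionMatrix, signature: SignatureDef
) -> tuple[pd.Series, float]:
    """Per-sample signature score: mean log2 expression of present genes.

    Returns the score series and the fraction of signature genes found.
    """
    present = [g for g in signature.gene_symbols if g in matrix.values.index]
    if not present:
        raise ValueError(
            f"no gene of signature {signature.name!r} is present in the matrix")
    frac = len(present) / len(signature.gene_symbols)
    score = matrix.values.loc[present].mean(axis=0)
    score.name = signature.name
    return score, frac


def correlate_scores_with_gene(
    scores: pd.DataFrame | pd.Series,
    matrix: ExpressionMatrix,
    gene: str,
    min_pairwise_n: int = 30,
) -> pd.DataFrame:
    """Pearson r (and two-sided p) of each score row against one gene.

    Shares the correlation machinery of the explorer; p is the usual
    t-distribution test on r with n - 2 degrees of freedom.
    """
    if isinstance(scores, pd.Series):
        scores = scores.to_frame().T
    shared = [s for s in scores.columns if s in matrix.values.columns]
    if len(shared) < min_pairwise_n:
        raise ValueError(
            f"only {len(shared)} shared samples between scores and matrix "
            f"(minimum {min_pairwise_n})")
    g = matrix.values.loc[gene, shared].to_numpy(dtype=float)
    out = []
    for name, row in scores[shared].iterrows():
        res = pearson_r2(row.to_numpy(dtype=float), g,
                         min_pairwise_n=min_pairwise_n,
                         x_name=str(name), y_name=gene)
        if res.degenerate or res.n_pairs < 3 or abs(res.r) == 1.0:
            p = 0.0 if abs(res.r) == 1.0 else 1.0
        else:
            t = res.r * math.sqrt((res.n_pairs - 2) / (1.0 - res.r2))
            p = 2.0 * stats.t.sf(abs(t), df=res.n_pairs - 2)
        out.append({"name": name, "pearson_r": res.r, "p": p,
                    "n": res.n_pairs})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Single-cell positivity
# ---------------------------------------------------------------------------

def cell_positivity(cells: CellProfileMatrix, gene: str) -> pd.Series:
    """Per-cell positivity call: log2(FPKM+1) >= threshold (inclusive).

    On the raw FPKM scale the default threshold 1.0 is FPKM >= 1.
    """
    if gene not in cells.values.index:
        raise KeyError(f"gene {gene!r} not in cell matrix")
    vals = cells.values.loc[gene]
    return (vals >= cells.positivity_threshold).rename(f"{gene}_positive")


def _exact_mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by label-permutation enumeration.

    Valid under ties (it is a permutation test on the U statistic); used when
    both groups have at most 8 observations.
    """
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    u1_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    mean_u = n1 * len(y) / 2.0
    dev_obs = abs(u1_obs - mean_u)
    total = 0
    extreme = 0
    idx = np.arange(len(pooled))
    for combo in combinations(idx, n1):
        u1 = float(ranks[list(combo)].sum() - n1 * (n1 + 1) / 2)
        total += 1
        if abs(u1 - mean_u) >= dev_obs - 1e-12:
            extreme += 1
    u_min = min(u1_obs, n1 * len(y) - u1_obs)
    return u_min, extreme / total


def mann_whitney(
    x: np.ndarray, y: np.ndarray, exact_max_n: int = 8
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact enumeration for small groups,
    otherwise normal approximation with mid-rank tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if len(x) <= exact_max_n and len(y) <= exact_max_n:
        return _exact_mannwhitney(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=False)
    u = min(float(res.statistic), len(x) * len(y) - float(res.statistic))
    return u, float(res.pvalue)


def compare_checkpoints_by_positivity(
    cells: CellProfileMatrix,
    target_gene: str,
    checkpoint_genes: Sequence[str],
) -> pd.DataFrame:
    """Per-checkpoint Mann-Whitney between target-positive and -negative
    cells, with direction and Benjamini-Hochberg adjusted p alongside raw p.
    """
    from statsmodels.stats.multitest import multipletests

    pos = cell_positivity(cells, target_gene).to_numpy()
    if pos.all() or not pos.any():
        raise ValueError(
            f"one positivity class of {target_gene!r} is empty")
    rows = []
    for cp in checkpoint_genes:
        if cp not in cells.values.index:
            raise KeyError(f"checkpoint gene {cp!r} not in cell matrix")
        v = cells.values.loc[cp].to_numpy(dtype=float)
        u, p = mann_whitney(v[pos], v[~pos])
        diff = float(np.median(v[pos]) - np.median(v[~pos]))
        if diff == 0.0:
            diff = float(v[pos].mean() - v[~pos].mean())
        rows.append({"checkpoint": cp, "u_statistic": u, "p": p,
                     "direction": "up" if diff > 0 else
                                  ("down" if diff < 0 else "none")})
    out = pd.DataFrame(rows)
    out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# Generic group statistics
# ---------------------------------------------------------------------------

def group_compare(
    values: np.ndarray, labels: Sequence, test: str
) -> tuple[float, float]:
    """Two-group or multi-group comparison.

    ``welch_t``: Welch's unequal-variance t (Welch-Satterthwaite df);
    ``mann_whitney``: two-sided rank test; ``anova``: one-way F.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if test in ("welch_t", "mann_whitney") and len(groups) != 2:
        raise ValueError(f"{test} requires exactly 2 groups, got {len(groups)}")
    if test == "welch_t":
        if any(len(g) < 2 for g in groups):
            raise ValueError("welch_t requires at least 2 values per group")
        res = stats.ttest_ind(groups[0], groups[1], equal_var=False)
        return float(res.statistic), float(res.pvalue)
    if test == "mann_whitney":
        return mann_whitney(groups[0], groups[1])
    if test == "anova":
        if len(groups) < 2 or any(len(g) < 2 for g in groups):
            raise ValueError("anova requires >=2 groups of >=2 values")
        res = stats.f_oneway(*groups)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def chi_squared_association(
    table: np.ndarray | pd.DataFrame,
) -> tuple[float, int, float]:
    """Pearson chi-squared on a two-way count table, no continuity
    correction; warns when any expected count is below 5."""
    counts = np.asarray(table, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise ValueError("zero row or column margin")
    chi2, p, dof, expected = stats.chi2_contingency(counts, correction=False)
    if (expected < 5).any():
        warnings.warn("chi-squared approximation dubious: expected count < 5",
                      stacklevel=2)
    return float(chi2), int(dof), float(p)


def anova_across_cell_types(
    cells: CellProfileMatrix, gene: str
) -> tuple[float, float]:
    """One-way ANOVA of a gene's log2(FPKM+1) values across cell types."""
    if gene not in cells.values.index:
        raise KeyError(f"gene {gene!r} not in cell matrix")
    vals = cells.values.loc[gene].to_numpy(dtype=float)
    types = cells.cell_types.to_numpy()
    groups = [vals[types == t] for t in pd.unique(types)]
    groups = [g for g in groups if len(g) >= 2]
    if len(groups) < 2:
        raise ValueError("need >=2 cell types with >=2 cells each")
    res = stats.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)
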
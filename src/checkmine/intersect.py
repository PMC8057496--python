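"""Combine per-seed feature lists into intersection reports.

Produces the gene x seed membership matrix, the >= m-of-K common-gene
report (ranked by overlap count, then maximum R^2 across lists, then
symbol), exclusive UpSet-style pattern counts, and cross-platform
commonality between two reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ga import FeatureList


@dataclass
class IntersectionTable:
    """Membership of every gene across the K seed lists.

    ``membership`` is a boolean gene x seed DataFrame; ``r2`` holds each
    gene's R^2 in the lists where it appears (NaN elsewhere).
    """

    membership: pd.DataFrame
    r2: pd.DataFrame
    m_threshold: int = 6

    def __post_init__(self) -> None:
        if (self.membership.sum(axis=1) < 1).any():
            raise ValueError("every listed gene must appear in >=1 list")

    @property
    def overlap_count(self) -> pd.Series:
        return self.membership.sum(axis=1).astype(int)

    @property
    def K(self) -> int:
        return self.membership.shape[1]

    @property
    def genes(self) -> list[str]:
        return list(self.membership.index)


def build_intersection_table(
    lists: Sequence[FeatureList], m_threshold: int = 6
) -> IntersectionTable:
    """Gene x seed membership from >=2 feature lists with distinct seeds."""
    if len(lists) < 2:
        raise ValueError("need at least 2 feature lists")
    seeds = [fl.seed_gene for fl in lists]
    if len(set(seeds)) != len(seeds):
        dupes = sorted({s for s in seeds if seeds.count(s) > 1})
        raise ValueError(f"duplicate seed genes across lists: {dupes}")
    genes = sorted({g for fl in lists for g in fl.genes})
    membership = pd.DataFrame(False, index=genes, columns=seeds)
    r2 = pd.DataFrame(np.nan, index=genes, columns=seeds)
    for fl in lists:
        for e in fl.entries:
            membership.loc[e.gene, fl.seed_gene] = True
            r2.loc[e.gene, fl.seed_gene] = e.r2
    return IntersectionTable(membership=membership, r2=r2,
                             m_threshold=m_threshold)


def report_common_genes(
    table: IntersectionTable, m_threshold: int | None = None
) -> pd.DataFrame:
    """Genes appearing in >= m of the K lists.

    Ranked by overlap count (desc), then maximum R^2 across lists (desc),
    then symbol (asc).  Columns: gene, overlap_count, max_r2.
    """
    m = table.m_threshold if m_threshold is None else m_threshold
    if not 1 <= m <= table.K:
        raise ValueError(f"m_threshold {m} outside [1, {table.K}]")
    counts = table.overlap_count
    keep = counts[counts >= m]
    max_r2 = table.r2.loc[keep.index].max(axis=1)
    out = pd.DataFrame({
        "gene": keep.index,
        "overlap_count": keep.to_numpy(),
        "max_r2": max_r2.to_numpy(),
    })
    out = out.sort_values(
        by=["overlap_count", "max_r2", "gene"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return out


def cross_platform_common(
    report_a: pd.DataFrame, report_b: pd.DataFrame
) -> list[str]:
    """Genes common to two reports, in report_a's ranking order."""
    in_b = set(report_b["gene"])
    return [g for g in report_a["gene"] if g in in_b]


def upset_exclusive_counts(table: IntersectionTable) -> dict[tuple[str, ...], int]:
    """Partition genes by their exact membership pattern.

    Keys are tuples of seed names (in table column order); values are the
    number of genes with exactly that pattern.  Counts sum to the number of
    distinct genes.
    """
    seeds = list(table.membership.columns)
    patterns: dict[tuple[str, ...], int] = {}
    for _, row in table.membership.iterrows():
        key = tuple(s for s in seeds if row[s])
        patterns[key] = patterns.get(key, 0) + 1
    return patterns


def exclusive_counts_frame(table: IntersectionTable) -> pd.DataFrame:
    """Plot-ready exclusive-pattern table: one row per pattern with a
    boolean column per seed plus the count, sorted by count descending."""
    patterns = upset_exclusive_counts(table)
    seeds = list(table.membership.columns)
    rows = []
    for key, count in patterns.items():
        row = {s: (s in key) for s in seeds}
        row["count"] = count
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values(
        by=["count", *seeds], ascending=False, kind="mergesort"
    ).reset_index(drop=True)
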
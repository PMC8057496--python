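"""Data model, file I/O, configuration and logging.

All on-disk formats are tab-separated UTF-8 text with ``NA`` as the missing
token, mirroring the Firehose-style exports the pipeline emulates.  Missing
values are carried as NaN in memory and are never silently coerced to zero.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("checkmine")

MISSING_TOKEN = "NA"
SEP = "\t"

#: Canonical nine-gene immune-checkpoint seed panel.
CHECKPOINT_SEEDS = (
    "PDL1", "PDCD1", "CTLA4", "LAG3", "TIM3", "TIGIT", "ICOS", "IDO1", "BTLA",
)


class Platform(str, enum.Enum):
    microarray = "microarray"
    rnaseq = "rnaseq"
    single_cell = "single_cell"


class ParseError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """log2-scale genes x samples expression table.

    ``values`` is a DataFrame indexed by gene symbol with sample-ID columns;
    missing entries are NaN.  Gene and sample identifiers must be unique and
    values must be finite where present.
    """

    values: pd.DataFrame
    platform: Platform = Platform.rnaseq

    def __post_init__(self) -> None:
        self.platform = Platform(self.platform)
        idx = self.values.index
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dupes[:5]}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        if self.values.shape[1] == 0:
            raise ValueError("expression matrix has zero samples")
        arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValueError("expression matrix contains infinite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene(self, symbol: str) -> np.ndarray:
        if symbol not in self.values.index:
            raise KeyError(f"gene {symbol!r} not in matrix")
        return self.values.loc[symbol].to_numpy(dtype=float)


def _check_rectangular(path: Path) -> None:
    n_fields = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            n = line.rstrip("\n").count(SEP) + 1
            if n_fields is None:
                n_fields = n
            elif n != n_fields:
                raise ParseError(
                    f"{path}: line {lineno} has {n} fields, expected {n_fields}"
                )


def read_expression_matrix(
    path: str | Path,
    platform: Platform | str = Platform.rnaseq,
    dedup: str = "median",
) -> ExpressionMatrix:
    """Read a tab-separated genes x samples matrix.

    First column holds gene symbols, the header row sample IDs.  Duplicate
    gene symbols are collapsed to the per-sample median (the microarray
    probe-collapse convention), ``NA``/blank cells become NaN.
    """
    path = Path(path)
    _check_rectangular(path)
    df = pd.read_csv(
        path, sep=SEP, index_col=0,
        na_values=[MISSING_TOKEN, ""], keep_default_na=False,
    )
    df.index = df.index.astype(str)
    if df.shape[1] == 0:
        raise ParseError(f"{path}: zero sample columns")
    df = df.astype(float)
    if df.index.has_duplicates:
        if dedup != "median":
            raise ValueError(f"unknown dedup policy {dedup!r}")
        order = df.index.drop_duplicates()
        df = df.groupby(level=0, sort=False).median().reindex(order)
    return ExpressionMatrix(values=df, platform=platform)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep=SEP, na_rep=MISSING_TOKEN,
                         index_label="gene", float_format="%.10g")


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

REQUIRED_CLINICAL = ("sample_id", "dfs_months", "dfs_event")
MSI_LEVELS = ("MSI-H", "MSS", "unknown")


@dataclass
class ClinicalTable:
    """Per-sample disease-free survival outcomes plus covariates.

    ``data`` carries one row per sample: ``sample_id``, ``dfs_months``
    (non-negative), ``dfs_event`` (boolean; True = recurrence/progression),
    an optional ``msi_status`` column and arbitrary covariate columns with
    NaN as the explicit missing marker.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_CLINICAL if c not in self.data.columns]
        if missing:
            raise ValueError(f"clinical table missing required columns: {missing}")
        if self.data["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in clinical table")
        if (self.data["dfs_months"].to_numpy(dtype=float) < 0).any():
            raise ValueError("dfs_months must be non-negative")
        self.data = self.data.reset_index(drop=True)
        self.data["dfs_event"] = _coerce_bool(self.data["dfs_event"])
        if "msi_status" in self.data.columns:
            bad = set(self.data["msi_status"].dropna()) - set(MSI_LEVELS)
            if bad:
                raise ValueError(f"unknown msi_status levels: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def covariate_columns(self) -> list[str]:
        skip = set(REQUIRED_CLINICAL)
        return [c for c in self.data.columns if c not in skip]

    def covariates(self) -> pd.DataFrame:
        return self.data[self.covariate_columns].copy()

    def __len__(self) -> int:
        return len(self.data)


def _coerce_bool(col: pd.Series) -> pd.Series:
    mapping = {"0": False, "1": True, "0.0": False, "1.0": True,
               "true": True, "false": False}
    out = []
    for v in col:
        if isinstance(v, (bool, np.bool_)):
            out.append(bool(v))
        elif isinstance(v, (int, float, np.integer, np.floating)):
            out.append(bool(int(v)))
        else:
            key = str(v).strip().lower()
            if key not in mapping:
                raise ValueError(f"cannot interpret dfs_event value {v!r}")
            out.append(mapping[key])
    return pd.Series(out, index=col.index, dtype=bool)


def read_clinical_table(path: str | Path) -> ClinicalTable:
    path = Path(path)
    df = pd.read_csv(path, sep=SEP, na_values=[MISSING_TOKEN, ""],
                     keep_default_na=False, dtype={"sample_id": str})
    missing = [c for c in REQUIRED_CLINICAL if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return ClinicalTable(data=df)


def write_clinical_table(table: ClinicalTable, path: str | Path) -> None:
    out = table.data.copy()
    out["dfs_event"] = out["dfs_event"].astype(int)
    out.to_csv(path, sep=SEP, na_rep=MISSING_TOKEN, index=False,
               float_format="%.10g")


# ---------------------------------------------------------------------------
# Signatures
# ---------------------------------------------------------------------------

@dataclass
class SignatureDef:
    name: str
    gene_symbols: list[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.gene_symbols:
            raise ValueError(f"signature {self.name!r} has no genes")
        if len(set(self.gene_symbols)) != len(self.gene_symbols):
            raise ValueError(f"signature {self.name!r} has duplicate symbols")


def read_signatures_gmt(path: str | Path) -> list[SignatureDef]:
    """Read GMT-format signatures: name <tab> description <tab> gene..."""
    sigs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(SEP)
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: expected name, "
                                 "description and at least one gene")
            sigs.append(SignatureDef(name=parts[0], description=parts[1],
                                     gene_symbols=[g for g in parts[2:] if g]))
    return sigs


def write_signatures_gmt(sigs: Sequence[SignatureDef], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sigs:
            fh.write(SEP.join([s.name, s.description, *s.gene_symbols]) + "\n")


# ---------------------------------------------------------------------------
# Feature lists and intersection tables
# ---------------------------------------------------------------------------

FEATURE_LIST_HEADER = ("seed_gene", "gene", "r", "r2", "passed")


def write_feature_list(flist, path: str | Path) -> None:
    """Write one seed's feature list: seed, candidate, r, R^2, pass flag.

    Rows are sorted by descending R^2; floats use repr precision so the file
    round-trips bit-exactly through :func:`read_feature_list`.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(SEP.join(FEATURE_LIST_HEADER) + "\n")
        fh.write(f"# platform={flist.platform.value}"
                 f"{SEP}coverage_at_export={flist.coverage_at_export!r}\n")
        for e in flist.entries:
            fh.write(SEP.join([flist.seed_gene, e.gene, repr(e.r), repr(e.r2),
                               "1"]) + "\n")


def read_feature_list(path: str | Path):
    from .ga import FeatureEntry, FeatureList  # local import avoids a cycle

    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(SEP)
        if tuple(header) != FEATURE_LIST_HEADER:
            raise ParseError(f"{path}: unexpected header {header}")
        meta_line = fh.readline().rstrip("\n")
        if not meta_line.startswith("#"):
            raise ParseError(f"{path}: missing metadata line")
        meta = dict(item.split("=", 1)
                    for item in meta_line.lstrip("# ").split(SEP))
        entries = []
        seed_gene = None
        for lineno, line in enumerate(fh, start=3):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(SEP)
            if len(parts) != len(FEATURE_LIST_HEADER):
                raise ParseError(f"{path}: line {lineno} malformed")
            seed_gene = parts[0]
            entries.append(FeatureEntry(gene=parts[1], r=float(parts[2]),
                                        r2=float(parts[3])))
    if seed_gene is None:
        seed_gene = path.stem
    return FeatureList(seed_gene=seed_gene, entries=entries,
                       platform=Platform(meta["platform"]),
                       coverage_at_export=float(meta["coverage_at_export"]))


def write_intersection_table(table, path: str | Path) -> None:
    """Write the gene x seed boolean membership matrix with overlap counts."""
    out = table.membership.astype(int).copy()
    out.insert(0, "overlap_count", table.overlap_count)
    out.to_csv(path, sep=SEP, index_label="gene")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline-wide settings; every stochastic stage draws from streams
    derived from ``rng_seed`` so runs are bit-reproducible."""

    rng_seed: int = 0
    significance_alpha: float = 0.05
    out_dir: str = "checkmine_out"
    stages: dict = field(default_factory=dict)
    clinical_allowlist: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 < self.significance_alpha < 1.0:
            raise ValueError("significance_alpha must lie in (0, 1)")


def load_run_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def derive_rng(rng_seed: int, *labels: str | int) -> np.random.Generator:
    """Deterministic, order-independent child stream for a labelled stage.

    Labels (e.g. a seed-gene symbol) are hashed with crc32 so the stream
    depends only on (rng_seed, labels), never on call order.
    """
    import zlib

    keys = [int(rng_seed)]
    for lab in labels:
        keys.append(zlib.crc32(str(lab).encode("utf-8")) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(keys))


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(levelname)s %(name)s: %(message)s",
    )
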
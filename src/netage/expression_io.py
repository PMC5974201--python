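"""Expression matrix I/O, probe collapsing, variance filtering and sample stratification.

The pipeline starts from normalized log-scale expression (e.g. an RMA-processed
GEO series matrix); raw probe-level preprocessing is out of scope.  This module
provides the canonical in-memory container (:class:`ExpressionDataset`), readers
for plain TSV matrices and GEO series-matrix text files, the IQR-based
probe-to-gene collapse, the variance filter used to restrict network
construction to varying genes, and the age/diagnosis stratification that splits
samples into young / aging / AD groups.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("young", "aging", "ad")


class ExpressionError(ValueError):
    """Raised for malformed expression inputs or contract violations."""


@dataclass
class ExpressionDataset:
    """Genes x samples matrix of normalized log-scale intensities plus metadata.

    Parameters
    ----------
    matrix
        DataFrame indexed by gene symbol, columns are sample IDs.
    sample_meta
        DataFrame indexed by sample ID with columns ``group`` (one of
        ``young``/``aging``/``ad`` or dataset-specific), ``age`` (years) and
        ``sex`` (``F``/``M``).
    """

    matrix: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.matrix.index.duplicated().any():
            dups = self.matrix.index[self.matrix.index.duplicated()].unique().tolist()
            raise ExpressionError(f"duplicate gene IDs: {dups[:5]}")
        if self.matrix.columns.duplicated().any():
            dups = self.matrix.columns[self.matrix.columns.duplicated()].unique().tolist()
            raise ExpressionError(f"duplicate sample IDs: {dups[:5]}")
        if self.matrix.isna().any().any():
            raise ExpressionError("expression matrix contains missing values")
        missing = [s for s in self.matrix.columns if s not in self.sample_meta.index]
        if missing:
            raise ExpressionError(f"samples without metadata: {missing[:5]}")
        self.sample_meta = self.sample_meta.loc[self.matrix.columns]
        if "group" in self.sample_meta and self.sample_meta["group"].isna().any():
            bad = self.sample_meta.index[self.sample_meta["group"].isna()].tolist()
            raise ExpressionError(f"samples without group label: {bad[:5]}")

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    @property
    def samples(self) -> pd.Index:
        return self.matrix.columns

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def group_samples(self, group: str) -> list[str]:
        mask = self.sample_meta["group"] == group
        return list(self.sample_meta.index[mask])

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        return ExpressionDataset(self.matrix.loc[list(genes)], self.sample_meta.copy())

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionDataset":
        return ExpressionDataset(
            self.matrix[list(samples)], self.sample_meta.loc[list(samples)]
        )

    def to_tsv(self, matrix_path: str | Path, meta_path: str | Path) -> None:
        """Write the matrix and metadata as the canonical pair of TSV files."""
        self.matrix.to_csv(matrix_path, sep="\t", index_label="gene")
        meta = self.sample_meta.copy()
        meta.index.name = "sample_id"
        meta.to_csv(meta_path, sep="\t")

    @classmethod
    def from_tsv(
        cls, matrix_path: str | Path, meta_path: str | Path
    ) -> "ExpressionDataset":
        matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(matrix, meta)


@dataclass
class TraitEncoding:
    """Numeric trait vectors aligned to a dataset's samples.

    ``stage`` is the ordinal disease-progression encoding (young 0, aging 1,
    AD 2); ``ad_indicator`` is binary (AD vs not); ``age`` is in years.
    """

    stage: pd.Series
    ad_indicator: pd.Series
    age: pd.Series

    STAGE_CODES = {"young": 0, "aging": 1, "ad": 2}

    @classmethod
    def from_dataset(cls, dataset: ExpressionDataset) -> "TraitEncoding":
        meta = dataset.sample_meta
        unknown = set(meta["group"]) - set(cls.STAGE_CODES)
        if unknown:
            raise ExpressionError(
                f"groups without a stage code: {sorted(unknown)}; expected {GROUPS}"
            )
        stage = meta["group"].map(cls.STAGE_CODES).astype(float)
        ad = (meta["group"] == "ad").astype(float)
        age = meta["age"].astype(float)
        return cls(stage=stage, ad_indicator=ad, age=age)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.age, "stage": self.stage, "ad": self.ad_indicator}
        )


def iqr(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Interquartile range Q3 - Q1 with linear quantile interpolation."""
    q1, q3 = np.percentile(values, [25, 75], axis=axis)
    return q3 - q1


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_expression(
    path: str | Path, format: str = "tsv"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a probe/gene-level matrix.

    Parameters
    ----------
    path
        File to read.
    format
        ``"tsv"`` for a plain matrix (first column IDs, header row of sample
        IDs) or ``"series_matrix"`` for the GEO series-matrix text format
        (``!`` directives plus the table between the table-begin/end markers).

    Returns
    -------
    matrix, sample_meta
        Probe/gene x sample matrix and a per-sample metadata frame (empty
        columns when the format carries none).
    """
    path = Path(path)
    if format == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        dup = sorted({c for c in header if header.count(c) > 1})
        if dup:  # pandas silently renames duplicates, so check the raw header
            raise ExpressionError(f"duplicated sample column ID(s): {dup}")
        matrix = pd.read_csv(path, sep="\t", index_col=0)
        _check_unique_samples(matrix)
        _check_numeric(matrix, path)
        meta = pd.DataFrame(index=matrix.columns)
        return matrix, meta
    if format == "series_matrix":
        return _read_series_matrix(path)
    raise ExpressionError(f"unknown format {format!r}; expected 'tsv' or 'series_matrix'")


def _check_unique_samples(matrix: pd.DataFrame) -> None:
    if matrix.columns.duplicated().any():
        dup = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise ExpressionError(f"duplicated sample column ID(s): {dup}")


def _check_numeric(matrix: pd.DataFrame, path: Path) -> None:
    nonnum = [c for c in matrix.columns if not np.issubdtype(matrix[c].dtype, np.number)]
    if nonnum:
        raise ExpressionError(f"{path}: non-numeric or ragged columns: {nonnum[:5]}")


def _read_series_matrix(path: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse the GEO series-matrix text format.

    Header directives are lines starting with ``!``; per-sample fields come
    from ``!Sample_*`` lines (tab-separated, double-quoted).  The expression
    table sits between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end``.
    """
    header: dict[str, list[list[str]]] = {}
    table_lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!Sample_"):
                key = line.split("\t", 1)[0][1:]
                values = [v.strip('"') for v in line.split("\t")[1:]]
                header.setdefault(key, []).append(values)
    if not table_lines:
        raise ExpressionError(f"{path}: no series_matrix table found")
    from io import StringIO

    matrix = pd.read_csv(StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    matrix.columns = [c.strip('"') for c in matrix.columns]
    matrix.index = [str(i).strip('"') for i in matrix.index]
    _check_unique_samples(matrix)

    meta = pd.DataFrame(index=matrix.columns)
    if "Sample_title" in header:
        meta["title"] = header["Sample_title"][0][: len(meta)]
    for row in header.get("Sample_characteristics_ch1", []):
        # rows look like "age: 35" / "sex: F" / "diagnosis: AD"
        keys = {v.split(":", 1)[0].strip().lower() for v in row if ":" in v}
        if len(keys) == 1:
            key = keys.pop()
            meta[key] = [v.split(":", 1)[1].strip() if ":" in v else None for v in row]
    if "age" in meta:
        meta["age"] = pd.to_numeric(meta["age"], errors="coerce")
    return matrix, meta


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ExpressionError(f"{path}:{ln}: GMT line has <3 fields")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name, *genes]) + "\n")


# ---------------------------------------------------------------------------
# Probe collapse / filtering / stratification
# ---------------------------------------------------------------------------

def collapse_probes(
    probe_matrix: pd.DataFrame,
    probe_to_gene: Mapping[str, Sequence[str] | str],
    sample_meta: pd.DataFrame | None = None,
) -> ExpressionDataset:
    """Collapse a probe-level matrix to one row per gene.

    Probes with no annotation or with multiple gene annotations are removed.
    Among probes annotated to the same single gene, the probe with the largest
    IQR across samples is retained.
    """
    rows: dict[str, tuple[float, str]] = {}
    values = probe_matrix.to_numpy(dtype=float)
    probe_iqr = dict(zip(probe_matrix.index, iqr(values, axis=1)))
    n_unannotated = n_multi = 0
    for probe in probe_matrix.index:
        genes = probe_to_gene.get(probe)
        if genes is None or (not isinstance(genes, str) and len(genes) == 0):
            n_unannotated += 1
            continue
        if not isinstance(genes, str):
            if len(genes) > 1:
                n_multi += 1
                continue
            genes = genes[0]
        cur = rows.get(genes)
        cand = (probe_iqr[probe], probe)
        if cur is None or cand > cur:
            rows[genes] = cand
    if not rows:
        raise ExpressionError("no annotated probes left after collapse")
    logger.info(
        "collapse_probes: dropped %d unannotated and %d multi-gene probes; kept %d genes",
        n_unannotated, n_multi, len(rows),
    )
    genes_sorted = sorted(rows)
    keep_probes = [rows[g][1] for g in genes_sorted]
    collapsed = probe_matrix.loc[keep_probes]
    collapsed.index = pd.Index(genes_sorted, name="gene")
    meta = sample_meta if sample_meta is not None else pd.DataFrame(index=probe_matrix.columns)
    return ExpressionDataset(collapsed, meta)


def iqr_filter(dataset: ExpressionDataset, threshold: float) -> ExpressionDataset:
    """Keep genes whose IQR across samples is strictly greater than *threshold*.

    Order of the surviving genes is preserved.
    """
    if threshold < 0:
        raise ExpressionError("IQR threshold must be >= 0")
    gene_iqr = iqr(dataset.matrix.to_numpy(dtype=float), axis=1)
    keep = gene_iqr > threshold
    if not keep.any():
        raise ExpressionError(
            f"IQR filter at {threshold} removed all {dataset.n_genes} genes; "
            "lower the threshold"
        )
    return ExpressionDataset(dataset.matrix.loc[keep], dataset.sample_meta.copy())


@dataclass
class StratifyRule:
    """Assigns a group to samples matching an age window and AD status.

    The defaults of :func:`stratify` encode the study design: young 20-50
    without AD, aging 70-99 without AD, AD 70-99 with a disease diagnosis.
    """

    group: str
    age_min: float
    age_max: float
    ad: bool

    def matches(self, age: float, ad: bool) -> bool:
        return self.age_min <= age <= self.age_max and ad == self.ad


DEFAULT_RULES = (
    StratifyRule("young", 20, 50, ad=False),
    StratifyRule("aging", 70, 99, ad=False),
    StratifyRule("ad", 70, 99, ad=True),
)


def stratify(
    dataset: ExpressionDataset,
    rules: Sequence[StratifyRule] = DEFAULT_RULES,
    ad_field: str = "diagnosis",
    ad_value: str | Callable[[str], bool] = "AD",
) -> ExpressionDataset:
    """Assign young/aging/ad group labels from age and diagnosis metadata.

    Samples matching no rule are excluded (count logged); a sample matching
    two rules is an error.
    """
    meta = dataset.sample_meta
    if "age" not in meta:
        raise ExpressionError("metadata lacks an 'age' field")
    if ad_field not in meta:
        raise ExpressionError(f"metadata lacks the {ad_field!r} field")
    if callable(ad_value):
        is_ad = meta[ad_field].map(ad_value)
    else:
        is_ad = meta[ad_field].astype(str).str.upper() == str(ad_value).upper()

    groups: dict[str, str] = {}
    for sample in meta.index:
        hits = [
            r.group
            for r in rules
            if r.matches(float(meta.at[sample, "age"]), bool(is_ad[sample]))
        ]
        if len(hits) > 1:
            raise ExpressionError(f"sample {sample} matches multiple groups: {hits}")
        if hits:
            groups[sample] = hits[0]
    excluded = [s for s in meta.index if s not in groups]
    if excluded:
        logger.info("stratify: excluded %d samples matching no rule", len(excluded))
    if not groups:
        raise ExpressionError("no samples matched any stratification rule")
    keep = [s for s in dataset.samples if s in groups]
    new_meta = meta.loc[keep].copy()
    new_meta["group"] = [groups[s] for s in keep]
    return ExpressionDataset(dataset.matrix[keep], new_meta)
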
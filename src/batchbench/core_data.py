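"""Data containers and TSV I/O for expression matrices and sample annotations.

Expression values are log2-scale probe-set intensities (post-summarization),
stored dense with genes as rows and samples as columns.  A sample sheet maps
every sample id to a batch label, a biological group label, and optionally a
replicate-group label plus arbitrary covariates.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NA_MARKER = "NA"
REQUIRED_SHEET_COLUMNS = ("batch", "group")


class DataValidationError(ValueError):
    """A matrix or sample sheet violates its structural contract."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise DataValidationError(f"duplicate {what}: {dups}")


@dataclass
class ExpressionMatrix:
    """Genes x samples grid of log2 expression intensities.

    Parameters
    ----------
    gene_ids : sequence of unique row identifiers (length G >= 1)
    sample_ids : sequence of unique column identifiers (length N >= 2)
    values : float array of shape (G, N), all finite
    """

    gene_ids: list
    sample_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        if self.values.ndim != 2:
            raise DataValidationError("values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataValidationError(
                f"value grid {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.gene_ids) < 1 or len(self.sample_ids) < 2:
            raise DataValidationError("need at least 1 gene and 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise DataValidationError("expression values must all be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        """Same ids, new value grid (must keep the shape)."""
        return ExpressionMatrix(list(self.gene_ids), list(self.sample_ids), values)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise DataValidationError(f"unknown sample ids: {missing}")
        idx = [pos[s] for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), sample_ids, self.values[:, idx])


@dataclass
class SampleSheet:
    """Per-sample annotations, indexed by sample id.

    The underlying frame always carries ``batch`` and ``group`` columns; an
    optional ``replicate_group`` column and any further columns are treated
    as covariates.  Every batch must contain at least two samples, since
    per-batch scale estimation is undefined for singletons.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        if df.index.name is None:
            df.index.name = "sample_id"
        df.index = df.index.astype(str)
        _check_unique(list(df.index), "sample ids")
        for col in REQUIRED_SHEET_COLUMNS:
            if col not in df.columns:
                raise DataValidationError(f"sample sheet missing required column {col!r}")
            if df[col].isna().any() or (df[col].astype(str) == "").any():
                raise DataValidationError(f"column {col!r} has empty entries")
        counts = df["batch"].value_counts()
        small = counts[counts < 2]
        if len(small):
            raise DataValidationError(
                f"every batch needs >= 2 samples; offending batch(es): {list(small.index)}"
            )
        self.data = df

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def batch(self) -> pd.Series:
        return self.data["batch"]

    @property
    def group(self) -> pd.Series:
        return self.data["group"]

    @property
    def batches(self) -> list:
        return group_levels(self.data["batch"])

    @property
    def covariate_columns(self) -> list:
        skip = set(REQUIRED_SHEET_COLUMNS) | {"replicate_group"}
        return [c for c in self.data.columns if c not in skip]

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        return SampleSheet(self.data.loc[list(sample_ids)])


def group_levels(series: pd.Series) -> list:
    """Category order if categorical, else order of first appearance."""
    if isinstance(series.dtype, pd.CategoricalDtype):
        return [c for c in series.cat.categories if c in set(series)]
    return list(dict.fromkeys(series))


def read_expression_tsv(path, min_present_fraction: float | None = None) -> ExpressionMatrix:
    """Read a genes-x-samples TSV (header = sample ids, column 1 = gene id).

    Missing entries are marked ``NA``.  With ``min_present_fraction`` set,
    genes observed in fewer than that fraction of samples are dropped; any
    missing entries remaining after the filter are an error (the container
    is dense).
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], "sample ids")   # read_csv silently renames dupes
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_MARKER],
                     keep_default_na=False, float_precision="round_trip")
    _check_unique(list(df.index), "gene ids")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise DataValidationError(f"non-numeric expression value in {path}: {exc}") from exc
    if min_present_fraction is not None:
        if not 0.0 <= min_present_fraction <= 1.0:
            raise DataValidationError("min_present_fraction must be in [0, 1]")
        present = df.notna().mean(axis=1)
        df = df.loc[present >= min_present_fraction]
        if df.empty:
            raise DataValidationError("present-call filter removed every gene")
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)].tolist()[:5]
        raise DataValidationError(
            f"missing values remain after filtering (e.g. genes {bad}); "
            "supply min_present_fraction or impute upstream"
        )
    return ExpressionMatrix.from_frame(df)


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    frame = expr.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t", na_rep=NA_MARKER)


def read_sample_sheet(path) -> SampleSheet:
    """Read a sample sheet TSV with columns sample_id, batch, group, ...

    Numeric covariate columns stay numeric; batch/group/replicate_group are
    always treated as categorical labels.
    """
    df = pd.read_csv(path, sep="\t", na_values=[NA_MARKER], keep_default_na=False)
    if "sample_id" not in df.columns:
        raise DataValidationError("sample sheet must have a 'sample_id' column")
    df = df.set_index("sample_id")
    for col in REQUIRED_SHEET_COLUMNS + ("replicate_group",):
        if col in df.columns:
            df[col] = df[col].astype(str)
    for col in df.columns:
        if col in REQUIRED_SHEET_COLUMNS or col == "replicate_group":
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        if not converted.isna().any():
            df[col] = converted
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.data.to_csv(path, sep="\t", na_rep=NA_MARKER)


def align(expr: ExpressionMatrix, sheet: SampleSheet, strict: bool = False):
    """Restrict matrix and sheet to their common samples, in matrix order.

    With ``strict`` on, a matrix sample missing from the sheet is an error
    rather than being silently dropped.
    """
    annotated = set(sheet.sample_ids)
    common = [s for s in expr.sample_ids if s in annotated]
    if not common:
        raise DataValidationError("matrix and sample sheet share no samples")
    unannotated = [s for s in expr.sample_ids if s not in annotated]
    if strict and unannotated:
        raise DataValidationError(f"samples without annotation: {unannotated}")
    return expr.subset_samples(common), sheet.subset(common)
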
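"""Expression-matrix I/O, quantile normalization and simple sample QC.

The assay consumes a probesets x samples matrix of *normalized log2
intensities* — i.e. the output of an upstream microarray preprocessing
pipeline (fRMA or similar).  This module does not reimplement array-level
preprocessing; :func:`quantile_normalize` is a convenience for raw-ish log2
matrices and :func:`qc_flag` computes four generic per-sample quality
surrogates (median intensity, IQR, fraction missing, correlation to the
cohort median profile), not a vendor-equivalent QC battery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, ParseError


class ExpressionMatrix:
    """Probesets x samples matrix of log2 intensities.

    Thin validated wrapper around a :class:`pandas.DataFrame` (rows =
    probesets, columns = samples).  Missing measurements are NaN.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dupes = sorted(data.index[data.index.duplicated()].unique().tolist())
            raise ParseError(f"duplicate probeset ids: {dupes}")
        if data.columns.has_duplicates:
            dupes = sorted(data.columns[data.columns.duplicated()].unique().tolist())
            raise ParseError(f"duplicate sample ids: {dupes}")
        data = data.astype(float)
        with np.errstate(invalid="ignore"):
            data = data.mask(~np.isfinite(data.to_numpy()))
        self.data = data
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.data.index.name = "probeset_id"

    @property
    def probeset_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, sample_ids].copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.data.equals(other.data)

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.shape[0]} probesets x {self.shape[1]} samples)"


def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read a tab-delimited probesets x samples table.

    First column = probeset_id, header row = sample ids, empty cells =
    missing.  Duplicate ids on either axis and ragged rows are parse errors.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"expression table not found: {path}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ncol = len(header)
        rows, index = [], []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != ncol:
                raise ParseError(
                    f"{path}:{lineno}: expected {ncol} fields, got {len(fields)}"
                )
            index.append(fields[0])
            rows.append([float(v) if v != "" else np.nan for v in fields[1:]])
    if not rows:
        raise ParseError(f"{path}: no data rows")
    frame = pd.DataFrame(rows, index=index, columns=header[1:])
    return ExpressionMatrix(frame)


def write_expression_table(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.data.to_csv(path, sep="\t", na_rep="", float_format="%.10g")


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Classical quantile normalization (mean quantile vector, ties averaged).

    After normalization every complete sample has the same sorted value
    vector: the across-sample mean of the order statistics.  Missing values
    stay missing and do not contribute to the reference vector of other
    rows' quantiles beyond being skipped within their own sample.  A single
    sample is returned unchanged with a warning.
    """
    df = expr.data
    if df.shape[1] < 2:
        warnings.warn("quantile normalization with a single sample is the identity")
        return ExpressionMatrix(df.copy())

    x = df.to_numpy(dtype=float)
    n_rows = x.shape[0]
    # Mean quantile vector over complete columns at each rank; columns with
    # missing values are normalized against the interpolated reference.
    sorted_cols = np.sort(x, axis=0)  # NaN sorts last
    counts = (~np.isnan(x)).sum(axis=0)
    ref = np.nanmean(sorted_cols, axis=1)  # length n_rows

    out = np.full_like(x, np.nan)
    for j in range(x.shape[1]):
        col = x[:, j]
        ok = ~np.isnan(col)
        k = counts[j]
        if k == 0:
            continue
        # average ranks for ties
        order = np.argsort(col[ok], kind="mergesort")
        ranks = np.empty(k, dtype=float)
        ranks[order] = np.arange(k)
        vals = col[ok]
        # tie groups share the mean reference value of their rank range
        ref_j = np.interp(
            np.linspace(0, n_rows - 1, k), np.arange(n_rows), ref
        ) if k != n_rows else ref
        mapped = ref_j[ranks.astype(int)]
        # average mapped values within tie groups
        s = pd.Series(mapped)
        tie_key = pd.Series(vals)
        mapped = s.groupby(tie_key, sort=False).transform("mean").to_numpy()
        out[ok, j] = mapped
    result = pd.DataFrame(out, index=df.index, columns=df.columns)
    return ExpressionMatrix(result)


@dataclass
class QCThresholds:
    """Cutoffs for the four per-sample QC surrogates."""

    max_fraction_missing: float = 0.5
    min_correlation: float = 0.5
    median_z: float = 4.0  # |z| of sample median vs cohort medians
    iqr_z: float = 4.0


@dataclass
class QCReport:
    metrics: pd.DataFrame = field(repr=False)
    thresholds: QCThresholds = field(default_factory=QCThresholds)

    @property
    def flagged(self) -> list[str]:
        return self.metrics.index[self.metrics["flagged"]].tolist()


def qc_flag(expr: ExpressionMatrix, thresholds: QCThresholds | None = None) -> QCReport:
    """Flag outlier samples on four deterministic surrogates.

    Metrics per sample: median intensity, IQR, fraction of missing values,
    and Pearson correlation of the profile to the cohort median profile.
    A sample is flagged when any metric crosses its threshold.
    """
    if expr.shape[0] == 0 or expr.shape[1] == 0:
        raise InputError("cannot QC an empty matrix")
    thr = thresholds or QCThresholds()
    df = expr.data
    med = df.median(axis=0, skipna=True)
    q75 = df.quantile(0.75)
    q25 = df.quantile(0.25)
    iqr = q75 - q25
    frac_missing = df.isna().mean(axis=0)
    ref = df.median(axis=1, skipna=True)
    corr = df.corrwith(ref)

    def robust_z(s: pd.Series) -> pd.Series:
        center = s.median()
        scale = (s - center).abs().median() * 1.4826
        if scale == 0 or np.isnan(scale):
            return pd.Series(0.0, index=s.index)
        return (s - center) / scale

    metrics = pd.DataFrame(
        {
            "median_intensity": med,
            "iqr": iqr,
            "fraction_missing": frac_missing,
            "correlation_to_median_profile": corr,
        }
    )
    metrics["flagged"] = (
        (frac_missing > thr.max_fraction_missing)
        | (corr.fillna(1.0) < thr.min_correlation)
        | (robust_z(med).abs() > thr.median_z)
        | (robust_z(iqr).abs() > thr.iqr_z)
    )
    metrics.index.name = "sample_id"
    return QCReport(metrics=metrics, thresholds=thr)


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited clinical/annotation table keyed by ``sample_id``."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"annotation table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: annotation table must have a sample_id column")
    if df["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample_id values")
    df["sample_id"] = df["sample_id"].astype(str)
    return df
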
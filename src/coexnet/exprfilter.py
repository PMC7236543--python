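"""FPKM expression matrices and low-expression filtering.

The filtering rule is the 3-sigma criterion commonly used when building
plant coexpression networks: take the 5th percentile of each sample's FPKM
distribution, average those percentiles across samples, add three standard
deviations, and drop every gene that stays below the resulting threshold in
*all* samples.  Genes that weak cannot yield meaningful correlation
coefficients downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ExpressionMatrixError(ValueError):
    """Raised when an expression matrix fails validation."""


@dataclass
class ExpressionMatrix:
    """A genes x samples FPKM table.

    Parameters
    ----------
    df
        DataFrame indexed by gene id with one column per sample.  All
        values must be finite, non-negative reals; gene and sample ids
        must be unique.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ExpressionMatrixError(f"duplicate gene ids: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = sorted(df.columns[df.columns.duplicated()].unique())
            raise ExpressionMatrixError(f"duplicate sample ids: {dups[:5]}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ExpressionMatrixError("non-numeric cells in expression matrix")
        if not np.isfinite(values).all():
            raise ExpressionMatrixError("non-finite FPKM values")
        if (values < 0).any():
            raise ExpressionMatrixError("negative FPKM values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.6g")


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read and strictly validate a TSV FPKM matrix.

    First column must be ``gene_id``; remaining columns are sample ids.
    Ragged rows, duplicate ids, negative or non-numeric cells are rejected.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows carry a line number
        raise ExpressionMatrixError(f"malformed expression TSV: {exc}") from exc
    if df.empty or df.shape[1] == 0:
        raise ExpressionMatrixError("expression matrix has no data columns")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ExpressionMatrixError(f"non-numeric FPKM cell: {exc}") from exc
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return ExpressionMatrix(df)


@dataclass
class FilterThreshold:
    """The 3-sigma low-expression threshold and its provenance.

    ``threshold = mean(per-sample p-th percentile) + sigma * sd`` with the
    unbiased (n-1) standard deviation taken across samples.
    """

    per_sample_p5: list[float]
    mean_p5: float
    sd_p5: float
    threshold: float
    percentile: float = 5.0
    sigma: float = 3.0

    def to_dict(self) -> dict:
        return {
            "per_sample_percentile": [float(v) for v in self.per_sample_p5],
            "mean": float(self.mean_p5),
            "sd": float(self.sd_p5),
            "threshold": float(self.threshold),
            "percentile": float(self.percentile),
            "sigma": float(self.sigma),
        }


def compute_fpkm_threshold(
    matrix: ExpressionMatrix,
    percentile: float = 5.0,
    sigma: float = 3.0,
    groups: dict[str, list[str]] | None = None,
) -> FilterThreshold | dict[str, FilterThreshold]:
    """Compute ``threshold = mean(p5) + sigma * sd(p5)`` across samples.

    The p-th percentile is taken per sample over all genes of that sample
    (zeros included) with linear interpolation; the mean and unbiased SD are
    taken across samples.  With ``groups`` (group name -> sample ids) a
    separate threshold is computed per experimental group.
    """
    if groups is not None:
        return {
            name: compute_fpkm_threshold(
                ExpressionMatrix(matrix.df[list(samples)]), percentile, sigma
            )
            for name, samples in groups.items()
        }
    values = matrix.values
    n_samples = values.shape[1]
    if n_samples < 2 and sigma != 0:
        raise ExpressionMatrixError(
            "at least 2 samples required for the SD term (or set sigma=0)"
        )
    p5 = np.percentile(values, percentile, axis=0)  # linear interpolation
    mean = float(np.mean(p5))
    sd = float(np.std(p5, ddof=1)) if n_samples > 1 else 0.0
    return FilterThreshold(
        per_sample_p5=[float(v) for v in p5],
        mean_p5=mean,
        sd_p5=sd,
        threshold=mean + sigma * sd,
        percentile=percentile,
        sigma=sigma,
    )


@dataclass
class RemovalReport:
    removed: list[str]
    retained: list[str]
    threshold: float
    retained_fraction: float = field(init=False)

    def __post_init__(self) -> None:
        total = len(self.removed) + len(self.retained)
        self.retained_fraction = len(self.retained) / total if total else 0.0

    def to_frame(self, matrix: ExpressionMatrix) -> pd.DataFrame:
        removed = set(self.removed)
        max_fpkm = matrix.df.max(axis=1)
        return pd.DataFrame(
            {
                "gene_id": matrix.gene_ids,
                "max_fpkm": [float(max_fpkm[g]) for g in matrix.gene_ids],
                "removed_flag": [int(g in removed) for g in matrix.gene_ids],
            }
        )


def filter_low_expression(
    matrix: ExpressionMatrix, threshold: FilterThreshold | float
) -> tuple[ExpressionMatrix, RemovalReport]:
    """Remove genes strictly below the threshold in every sample.

    A gene reaching the threshold in even one sample is retained.  The
    sample set is never altered.
    """
    cut = threshold.threshold if isinstance(threshold, FilterThreshold) else float(threshold)
    below_everywhere = (matrix.df < cut).all(axis=1)
    removed = list(matrix.df.index[below_everywhere])
    kept = matrix.df.loc[~below_everywhere]
    report = RemovalReport(removed=removed, retained=list(kept.index), threshold=cut)
    return ExpressionMatrix(kept), report
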
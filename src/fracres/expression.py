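"""RPKM expression matrices: max-reduction, top-percentile filter, binning.

RNA-seq expression is taken per gene as the *maximum* RPKM over all
conditions/tissues, on the grounds that many genes are expressed only in
specific tissues and the peak level best reflects a gene's importance.  To
keep a handful of extremely highly expressed genes from swamping category
averages, genes in the top 1% of expression are removed before any
expression analysis.  For distributional comparisons, log10(RPKM + 1)
values are collected into equal-width bins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionTable",
    "BinScheme",
    "read_expression",
    "max_expression",
    "filter_top_percent",
    "log_transform",
    "assign_bins",
]


class ExpressionTable:
    """A gene x condition matrix of RPKM values.

    Wraps a pandas DataFrame (index = gene ids, columns = condition names)
    and validates that every cell is a finite non-negative number and no
    gene appears twice.
    """

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene row(s): {dups[:5]}")
        numeric = values.apply(pd.to_numeric, errors="coerce")
        if numeric.isna().any().any():
            bad = values.columns[numeric.isna().any()].tolist()
            raise ValueError(f"non-numeric cell(s) in column(s) {bad[:5]}")
        arr = numeric.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite RPKM value in expression matrix")
        if (arr < 0).any():
            raise ValueError("negative RPKM value in expression matrix")
        self.values = numeric.astype(float)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def conditions(self) -> pd.Index:
        return self.values.columns

    @property
    def per_gene_max(self) -> pd.Series:
        return max_expression(self)

    def log_max(self, pseudocount: float = 1.0) -> pd.Series:
        return log_transform(self.per_gene_max, pseudocount)


def read_expression(path: str | Path) -> ExpressionTable:
    """Read a ``gene_id<TAB>cond1<TAB>...`` numeric RPKM table."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionTable(df)


def max_expression(table: ExpressionTable) -> pd.Series:
    """Per-gene maximum RPKM over all conditions."""
    return table.values.max(axis=1)


def log_transform(per_gene_max: pd.Series, pseudocount: float = 1.0) -> pd.Series:
    """log10(RPKM + pseudocount); the pseudocount keeps zeros finite."""
    return np.log10(per_gene_max + pseudocount)


def filter_top_percent(
    per_gene_max: pd.Series, percent: float = 1.0
) -> tuple[pd.Index, float]:
    """Drop genes in the top ``percent`` of expression (nearest-rank rule).

    The threshold is the nearest-rank upper percentile of the per-gene
    maxima; genes *strictly above* it are removed, so full ties remove
    nothing.  Returns ``(retained gene index, threshold)``.  With fewer
    than ``100 / percent`` genes the filter cannot resolve the percentile
    and removes nothing (with a warning).
    """
    if not 0 < percent < 100:
        raise ValueError("percent must be in (0, 100)")
    n = len(per_gene_max)
    if n < 100.0 / percent:
        warnings.warn(
            f"only {n} genes: top-{percent}% filter has no resolution, "
            "keeping all genes",
            stacklevel=2,
        )
        return per_gene_max.index, float("inf")
    rank = math.ceil((100.0 - percent) / 100.0 * n)  # 1-based nearest rank
    threshold = float(np.sort(per_gene_max.to_numpy())[rank - 1])
    retained = per_gene_max.index[per_gene_max.to_numpy() <= threshold]
    return retained, threshold


@dataclass(frozen=True)
class BinScheme:
    """Equal-membership rule for log-expression bins.

    ``edges`` are ascending breakpoints; bin i is the half-open interval
    [edges[i], edges[i+1]), with the last bin closed so the maximum value
    is included.
    """

    edges: tuple[float, ...]

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=float)
        if len(e) < 2 or not np.all(np.diff(e) > 0):
            raise ValueError("edges must be >= 2 strictly increasing values")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @classmethod
    def from_data(cls, values, n_bins: int = 8) -> "BinScheme":
        """Equal-width bins spanning the observed range.

        A degenerate (constant) range is widened by 1 so the scheme stays
        valid and every value lands in bin 0.
        """
        arr = np.asarray(values, dtype=float)
        lo, hi = float(arr.min()), float(arr.max())
        if hi <= lo:
            hi = lo + 1.0
        return cls(edges=tuple(np.linspace(lo, hi, n_bins + 1)))

    def assign(self, values) -> np.ndarray:
        """Vector bin assignment; values outside the edges are an error."""
        arr = np.asarray(values, dtype=float)
        if arr.size and (arr.min() < self.edges[0] or arr.max() > self.edges[-1]):
            raise ValueError("value outside bin edges (edges should span the data)")
        idx = np.searchsorted(self.edges, arr, side="right") - 1
        return np.clip(idx, 0, self.n_bins - 1)


def assign_bins(log_max: Mapping[str, float] | pd.Series, scheme: BinScheme) -> pd.Series:
    """Map each gene's log expression to its bin index."""
    series = pd.Series(log_max, dtype=float)
    return pd.Series(scheme.assign(series.to_numpy()), index=series.index)
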
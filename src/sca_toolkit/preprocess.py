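"""Filtering and normalization for UMI count matrices.

The pipeline order is: present-gene call (>= min_umi UMIs), low-quality
cell removal (cells with fewer than ``min_present_genes`` present genes),
then gene selection (the ``top_variant`` most variant genes out of the
``top_expressed`` most expressed). Normalization is CPM / log2CPM and
row-mean centering of expression profiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io import CountMatrix

logger = logging.getLogger(__name__)


class EmptyResultError(ValueError):
    """Raised when a filter removes every cell or gene."""


@dataclass
class PresenceMatrix:
    """Boolean features x cells matrix: entry true iff count >= min_umi."""

    values: np.ndarray
    min_umi: int = 3

    @property
    def genes_per_cell(self) -> np.ndarray:
        return self.values.sum(axis=0)


@dataclass
class ExpressionMatrix:
    """features x cells real-valued expression after normalization.

    ``transform_tag`` records the last transform applied:
    one of ``raw``, ``cpm``, ``log2cpm``, ``centered``.
    """

    values: np.ndarray
    feature_ids: list[str]
    cell_ids: list[str]
    transform_tag: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.cell_ids)):
            raise ValueError("shape/ID mismatch in ExpressionMatrix")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.cell_ids)


def call_present(m: CountMatrix, min_umi: int = 3) -> PresenceMatrix:
    """Call a gene present in a cell when supported by >= ``min_umi`` UMIs.

    The default of 3 moderates the effect of sequencing errors in UMI
    counting that one or two stray UMIs would otherwise introduce.
    """
    if min_umi < 1:
        raise ValueError("min_umi must be >= 1")
    return PresenceMatrix(m.values >= min_umi, min_umi)


def filter_cells(m: CountMatrix, min_present_genes: int, min_umi: int = 3) -> CountMatrix:
    """Remove low-quality cells: keep cells with >= ``min_present_genes``
    present genes (>= ``min_umi`` UMIs each). Cell order is preserved."""
    if min_present_genes < 0:
        raise ValueError("min_present_genes must be >= 0")
    present = call_present(m, min_umi)
    keep = present.genes_per_cell >= min_present_genes
    n_kept = int(keep.sum())
    if n_kept == 0:
        raise EmptyResultError(
            f"all {m.n_cells} cells removed (min_present_genes={min_present_genes}, "
            f"min_umi={min_umi}); max present-gene count was "
            f"{int(present.genes_per_cell.max(initial=0))}"
        )
    logger.info("filter_cells: kept %d/%d cells", n_kept, m.n_cells)
    return CountMatrix(
        m.values[:, keep],
        m.feature_ids,
        [c for c, k in zip(m.cell_ids, keep) if k],
    )


def select_genes(m: CountMatrix, top_expressed: int = 5000, top_variant: int = 2500) -> CountMatrix:
    """Two-stage gene selection: the ``top_variant`` most variant genes out
    of the ``top_expressed`` most expressed.

    Expression rank = total raw count across cells; variance rank = sample
    variance of raw counts across cells. Ties break toward the earlier
    input row; the original row order is preserved among survivors.
    """
    if not (0 < top_variant <= top_expressed <= m.n_features):
        raise ValueError(
            f"need 0 < top_variant ({top_variant}) <= top_expressed ({top_expressed}) "
            f"<= n_features ({m.n_features})"
        )
    totals = m.values.sum(axis=1)
    # stable sort on -totals keeps input order among ties
    expressed = np.sort(np.argsort(-totals, kind="stable")[:top_expressed])
    variances = m.values[expressed].var(axis=1, ddof=1) if m.n_cells > 1 else np.zeros(len(expressed))
    chosen = expressed[np.sort(np.argsort(-variances, kind="stable")[:top_variant])]
    return CountMatrix(
        m.values[chosen],
        [m.feature_ids[i] for i in chosen],
        m.cell_ids,
    )


def restrict_to_genes(
    m: CountMatrix, gene_ids, allow_missing: bool = False
) -> CountMatrix:
    """Subset and reorder rows to ``gene_ids``.

    With ``allow_missing`` the intersection (in ``gene_ids`` order) is
    returned and the missing IDs are logged; otherwise they are an error.
    """
    index = {g: i for i, g in enumerate(m.feature_ids)}
    gene_ids = list(gene_ids)
    missing = [g for g in gene_ids if g not in index]
    if missing and not allow_missing:
        raise KeyError(f"{len(missing)} requested genes absent, e.g. {missing[:5]}")
    if missing:
        logger.warning("restrict_to_genes: dropping %d absent genes", len(missing))
    kept = [g for g in gene_ids if g in index]
    if not kept:
        raise EmptyResultError("no requested genes present in the matrix")
    rows = [index[g] for g in kept]
    return CountMatrix(m.values[rows], kept, m.cell_ids)


def _as_expression(values, m, tag: str) -> ExpressionMatrix:
    feature_ids = list(m.feature_ids)
    cell_ids = list(m.cell_ids)
    return ExpressionMatrix(values, feature_ids, cell_ids, tag)


def cpm(m: CountMatrix | ExpressionMatrix) -> ExpressionMatrix:
    """Counts per million: scale each column to sum to 1e6.

    Columns with zero total map to all-zero columns (with a warning).
    """
    values = np.asarray(m.values, dtype=float)
    if values.size and values.min() < 0:
        raise ValueError("cpm requires nonnegative input")
    colsums = values.sum(axis=0)
    zero = colsums == 0
    if zero.any():
        warnings.warn(f"cpm: {int(zero.sum())} zero-sum columns map to all-zero columns")
    scale = np.divide(1e6, colsums, out=np.zeros_like(colsums, dtype=float), where=~zero)
    return _as_expression(values * scale, m, "cpm")


def log2cpm(m: CountMatrix | ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(CPM + pseudocount); the pseudocount guards zero entries."""
    out = cpm(m)
    out.values = np.log2(out.values + pseudocount)
    out.transform_tag = "log2cpm"
    return out


def row_mean_center(m: CountMatrix | ExpressionMatrix) -> ExpressionMatrix:
    """Center each gene (row) on its mean across profiles."""
    values = np.asarray(m.values, dtype=float)
    return _as_expression(values - values.mean(axis=1, keepdims=True), m, "centered")
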
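"""Cluster-level pseudo-bulk generation with a cluster-conditioned SCA.

Orientation: training samples are genes, input features are cells, and the
hidden layer has one node per cluster, connected only to that cluster's
cells. The hidden activation of gene g at cluster node c is a modeled
average expression of g over the cells of c — a pseudo-bulk. Repeating the
training with fresh initializations yields pseudo-replicates; unlike raw
single-cell profiles these are not zero-inflated, which is what makes them
usable with conventional bulk RNA-seq machinery downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io import ClusterAssignment, CountMatrix
from .model import ConnectivityMask, SCAConfig, run_permutations, scale_input
from .preprocess import ExpressionMatrix, log2cpm, row_mean_center

logger = logging.getLogger(__name__)


@dataclass
class PseudoBulkSet:
    """genes x (cluster, run) hidden-layer activations as pseudo-counts."""

    values: np.ndarray
    gene_ids: list[str]
    cluster_labels: list[str]
    n_runs: int

    def __post_init__(self) -> None:
        expected = len(self.cluster_labels) * self.n_runs
        if self.values.shape != (len(self.gene_ids), expected):
            raise ValueError(
                f"pseudo-bulk shape {self.values.shape} != "
                f"({len(self.gene_ids)}, {expected})"
            )
        if self.values.size and self.values.min() < 0:
            raise ValueError("pseudo-bulk values must be nonnegative")

    @property
    def column_labels(self) -> list[tuple[str, int]]:
        """(cluster_label, run_index) per column; runs vary slowest."""
        return [
            (lab, r)
            for r in range(self.n_runs)
            for lab in self.cluster_labels
        ]

    @property
    def column_names(self) -> list[str]:
        return [f"{lab}.{r}" for lab, r in self.column_labels]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.column_names)


def cluster_membership_mask(
    assignment: ClusterAssignment, cell_ids: list[str]
) -> ConnectivityMask:
    """clusters x cells binary mask; rows partition the assigned cells.

    Cells absent from the assignment are dropped (with a warning); a
    cluster left with zero cells after the intersection is an error.
    """
    assigned = [c for c in cell_ids if c in assignment.mapping]
    dropped = len(cell_ids) - len(assigned)
    if dropped:
        warnings.warn(f"{dropped} cells have no cluster assignment and are dropped")
    if not assigned:
        raise ValueError("no cell in the matrix has a cluster assignment")
    labels = [lab for lab in assignment.labels if any(assignment.mapping[c] == lab for c in assigned)]
    lost = set(assignment.labels) - set(labels)
    if lost:
        raise ValueError(f"clusters with zero cells after intersection: {sorted(lost)}")
    row = {lab: i for i, lab in enumerate(labels)}
    values = np.zeros((len(labels), len(assigned)))
    for j, cell in enumerate(assigned):
        values[row[assignment.mapping[cell]], j] = 1.0
    return ConnectivityMask(values, labels, assigned)


def pseudobulk_replicates(
    m: CountMatrix,
    assignment: ClusterAssignment,
    config: SCAConfig | None = None,
    n_runs: int = 20,
) -> PseudoBulkSet:
    """Generate ``n_runs`` pseudo-bulk replicates per cluster.

    The count matrix is transposed (genes become training samples), the
    input is log1p-transformed and min-max scaled per cell, and each run
    is an independent SCA training; run r of cluster c fills column
    (c, r). Deterministic given ``config.base_seed``.
    """
    config = config or SCAConfig()
    mask = cluster_membership_mask(assignment, m.cell_ids)
    small = [lab for lab in mask.metafeature_ids
             if int(mask.values[mask.metafeature_ids.index(lab)].sum()) < 2]
    if small:
        warnings.warn(f"clusters with <2 cells: {small}; pseudo-bulk still produced")
    # restrict columns to assigned cells, in mask order
    col = {c: j for j, c in enumerate(m.cell_ids)}
    data = m.values[:, [col[c] for c in mask.feature_ids]]
    x = scale_input(data, counts=True)  # samples=genes, features=cells
    results = run_permutations(x, mask, config, n_runs=n_runs)
    blocks = [res.hidden for res in results]  # each genes x clusters
    values = np.hstack(blocks)
    return PseudoBulkSet(values, list(m.feature_ids), mask.metafeature_ids, n_runs)


def summarize_pseudobulk(pb: PseudoBulkSet, mode: str = "per_run") -> ExpressionMatrix:
    """log2CPM + row-mean centering of the pseudo-bulk profiles.

    ``per_run`` keeps every replicate column; ``mean_over_runs`` first
    averages each cluster's replicates into a single profile.
    """
    if mode == "per_run":
        values = pb.values
        names = pb.column_names
    elif mode == "mean_over_runs":
        k = len(pb.cluster_labels)
        stacked = pb.values.reshape(pb.values.shape[0], pb.n_runs, k)
        values = stacked.mean(axis=1)
        names = list(pb.cluster_labels)
    else:
        raise ValueError("mode must be 'per_run' or 'mean_over_runs'")
    em = ExpressionMatrix(values, list(pb.gene_ids), names, "raw")
    return row_mean_center(log2cpm(em))


def naive_pseudobulk(m: CountMatrix, assignment: ClusterAssignment) -> ExpressionMatrix:
    """Baseline pseudo-bulk: sum raw counts of each gene over each
    cluster's cells. Conserves total counts per gene exactly."""
    mask = cluster_membership_mask(assignment, m.cell_ids)
    col = {c: j for j, c in enumerate(m.cell_ids)}
    data = m.values[:, [col[c] for c in mask.feature_ids]]
    sums = data @ mask.values.T  # genes x clusters
    return ExpressionMatrix(sums, list(m.feature_ids), mask.metafeature_ids, "raw")
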
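"""TF/miRNA metagene matrices by cumulative summation of SCA hidden layers.

Samples are cells, hidden nodes are metafeatures (TFs or miRNAs), and the
mask comes from metafeature -> target-gene relationships. Because the
hidden layer keeps the informative part of the signal while discarding
much of the noise, summing it over many independently trained runs
progressively amplifies metafeatures that distinguish cell subpopulations
while the uninformative ones stay near background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ClusterAssignment, CountMatrix, RelationshipTable
from .model import SCAConfig, build_mask, run_permutations, scale_input
from .preprocess import restrict_to_genes


@dataclass
class MetageneMatrix:
    """cells x metafeatures cumulative hidden-layer sums over runs."""

    values: np.ndarray
    cell_ids: list[str]
    metafeature_ids: list[str]
    n_runs_summed: int

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.cell_ids), len(self.metafeature_ids)):
            raise ValueError("metagene matrix shape/ID mismatch")
        if self.values.size and self.values.min() < 0:
            raise ValueError("metagene values must be nonnegative")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.metafeature_ids)


def metagene_matrix(
    m: CountMatrix,
    rel: RelationshipTable,
    config: SCAConfig | None = None,
    n_runs: int = 100,
    mean: bool = False,
    keep_runs: bool = False,
) -> MetageneMatrix | tuple[MetageneMatrix, list[np.ndarray]]:
    """Build the cells x metafeatures matrix from ``n_runs`` SCA trainings.

    The mask is binarized against the matrix's genes (features connected
    to no metafeature are dropped from the model input); the input is
    log1p + per-gene min-max scaled; the result is the entrywise sum of
    the runs' hidden layers (or the mean with ``mean=True``).
    ``keep_runs`` additionally returns each run's cells x metafeatures
    activations.
    """
    config = config or SCAConfig()
    mask = build_mask(rel, m.feature_ids, drop_unconnected=True)
    sub = restrict_to_genes(m, mask.feature_ids)
    x = scale_input(sub.values.T, counts=True)  # cells x genes
    results = run_permutations(x, mask, config, n_runs=n_runs)
    runs = [res.hidden for res in results]
    total = np.sum(runs, axis=0)
    if mean:
        total = total / n_runs
    mm = MetageneMatrix(total, list(m.cell_ids), mask.metafeature_ids, n_runs)
    if keep_runs:
        return mm, runs
    return mm


def kmeans_convenience(mm: MetageneMatrix, k: int, seed: int = 0) -> ClusterAssignment:
    """Seeded k-means (k-means++ init) on the metagene matrix.

    A convenience for end-to-end runs without an external clustering tool.
    Labels are ``m1..mk`` in decreasing cluster-size order.
    """
    from sklearn.cluster import KMeans

    n = len(mm.cell_ids)
    if k < 2 or k > n:
        raise ValueError(f"need 2 <= k <= n_cells ({n})")
    if k > np.unique(mm.values, axis=0).shape[0]:
        raise ValueError("k exceeds the number of distinct rows")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    raw = km.fit_predict(mm.values)
    sizes = np.bincount(raw, minlength=k)
    # size-ranked relabeling, ties by original label index
    order = np.lexsort((np.arange(k), -sizes))
    rename = {int(old): f"m{rank + 1}" for rank, old in enumerate(order)}
    return ClusterAssignment({c: rename[int(lab)] for c, lab in zip(mm.cell_ids, raw)})
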
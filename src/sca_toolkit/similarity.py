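"""Pearson similarity between expression profiles, best-match cluster
pairing across experiments, and Euclidean / average-linkage (UPGMA)
hierarchical clustering for cell-type assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance

from .preprocess import ExpressionMatrix


def strip_ensembl_version(gene_id: str) -> str:
    """ENSG00000123456.7 -> ENSG00000123456 (cross-dataset ID matching)."""
    head, _, tail = gene_id.rpartition(".")
    if head.startswith("ENS") and tail.isdigit():
        return head
    return gene_id


@dataclass
class SimilarityMatrix:
    """n x m Pearson correlations between two sets of profiles.

    Entries are in [-1, 1]; a zero-variance profile yields NaN entries
    (reported, never silently zero).
    """

    values: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels)

    def plot(self, ax=None, cmap: str = "RdBu_r"):
        """Heatmap of the similarity matrix (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(1 + 0.5 * len(self.col_labels),
                                          1 + 0.5 * len(self.row_labels)))
        im = ax.imshow(self.values, vmin=-1, vmax=1, cmap=cmap)
        ax.set_xticks(range(len(self.col_labels)), self.col_labels, rotation=90)
        ax.set_yticks(range(len(self.row_labels)), self.row_labels)
        ax.figure.colorbar(im, ax=ax, label="Pearson r")
        return ax


def pearson_matrix(
    a: ExpressionMatrix,
    b: ExpressionMatrix,
    strip_versions: bool = True,
) -> SimilarityMatrix:
    """Pearson correlation of every column of ``a`` with every column of
    ``b`` over their shared features.

    Features are intersected by ID (Ensembl version suffixes stripped by
    default) and used in a fixed sorted order; at least 3 shared features
    are required.
    """
    key = strip_ensembl_version if strip_versions else (lambda g: g)
    idx_a = {key(g): i for i, g in enumerate(a.feature_ids)}
    idx_b = {key(g): i for i, g in enumerate(b.feature_ids)}
    shared = sorted(set(idx_a) & set(idx_b))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared features; need >= 3")
    xa = a.values[[idx_a[g] for g in shared]].astype(float)
    xb = b.values[[idx_b[g] for g in shared]].astype(float)

    xa = xa - xa.mean(axis=0, keepdims=True)
    xb = xb - xb.mean(axis=0, keepdims=True)
    sa = np.sqrt((xa**2).sum(axis=0))
    sb = np.sqrt((xb**2).sum(axis=0))
    bad_a, bad_b = sa == 0, sb == 0
    if bad_a.any() or bad_b.any():
        bad = [a.cell_ids[i] for i in np.where(bad_a)[0]] + [
            b.cell_ids[j] for j in np.where(bad_b)[0]
        ]
        warnings.warn(f"zero-variance profiles yield NaN correlations: {bad}")
    sa[bad_a] = 1.0
    sb[bad_b] = 1.0
    r = (xa.T @ xb) / np.outer(sa, sb)
    r = np.clip(r, -1.0, 1.0)
    r[bad_a, :] = np.nan
    r[:, bad_b] = np.nan
    return SimilarityMatrix(r, list(a.cell_ids), list(b.cell_ids))


def best_match(s: SimilarityMatrix, tie_tol: float = 1e-12) -> pd.DataFrame:
    """Row-directional best-match pairing (the heatmap "arrows").

    For each row profile: the argmax column, its r, the runner-up r and
    the margin. Rows whose top two correlations are within ``tie_tol``
    are flagged ambiguous rather than broken arbitrarily.
    """
    rows = []
    for i, lab in enumerate(s.row_labels):
        r = s.values[i]
        finite = np.isfinite(r)
        if not finite.any():
            rows.append((lab, None, np.nan, np.nan, np.nan, True))
            continue
        order = np.argsort(np.where(finite, r, -np.inf))[::-1]
        j = order[0]
        runner = r[order[1]] if len(order) > 1 and np.isfinite(r[order[1]]) else np.nan
        margin = r[j] - runner if np.isfinite(runner) else np.inf
        ambiguous = bool(np.isfinite(runner) and margin <= tie_tol)
        rows.append((lab, s.col_labels[j], float(r[j]), float(runner) if np.isfinite(runner) else np.nan,
                     float(margin) if np.isfinite(margin) else np.inf, ambiguous))
    return pd.DataFrame(
        rows, columns=["query", "best_match", "r", "runner_up_r", "margin", "ambiguous"]
    )


@dataclass
class Dendrogram:
    """UPGMA merge history: (node_a, node_b, height, new_node_id) per merge.

    Leaves are 0..n-1 in label order; merge i creates node n+i. Heights
    are non-decreasing (UPGMA on a metric).
    """

    merges: list[tuple[int, int, float, int]]
    leaf_labels: list[str]

    @property
    def linkage(self) -> np.ndarray:
        """scipy-style linkage matrix (with cluster sizes recomputed)."""
        n = len(self.leaf_labels)
        sizes = {i: 1 for i in range(n)}
        out = np.zeros((len(self.merges), 4))
        for k, (a, b, h, new) in enumerate(self.merges):
            sizes[new] = sizes[a] + sizes[b]
            out[k] = [a, b, h, sizes[new]]
        return out

    def to_newick(self) -> str:
        n = len(self.leaf_labels)
        reps: dict[int, tuple[str, float]] = {
            i: (lab, 0.0) for i, lab in enumerate(self.leaf_labels)
        }
        for a, b, h, new in self.merges:
            (sa, ha), (sb, hb) = reps.pop(a), reps.pop(b)
            reps[new] = (f"({sa}:{h / 2 - ha:.6g},{sb}:{h / 2 - hb:.6g})", h / 2)
        (tree, _), = reps.values()
        return tree + ";"


def upgma(profiles: ExpressionMatrix) -> Dendrogram:
    """Average-linkage hierarchical clustering of profiles (columns) under
    Euclidean distance, with deterministic index-order tie-breaking."""
    x = np.asarray(profiles.values, dtype=float).T  # profiles as rows
    if x.shape[0] < 2:
        raise ValueError("need >= 2 profiles")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in profiles")
    d = scipy.spatial.distance.pdist(x, metric="euclidean")
    z = scipy.cluster.hierarchy.linkage(d, method="average")
    n = x.shape[0]
    merges = [
        (int(a), int(b), float(h), n + k) for k, (a, b, h, _size) in enumerate(z)
    ]
    return Dendrogram(merges, list(profiles.cell_ids))
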
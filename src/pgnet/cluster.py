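"""Hierarchical clustering of miRNA tissue-expression profiles.

Rows (miRNAs) are z-scored before any distance computation, then clustered
with agglomerative linkage (average by default) under either a
1 - Pearson-correlation or a Euclidean distance.  Columns (tissues) are
clustered the same way for display ordering.  Cutting the row dendrogram
at a chosen cluster count yields the group labels; constant rows, whose
z-score is undefined, are held out and assigned to the nearest cluster
centroid afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io import ExpressionMatrix


class ClusterError(ValueError):
    pass


@dataclass
class ClusterResult:
    """Row/column orders, row labels at the cut, and merge histories."""

    row_order: list[str]
    col_order: list[str]
    row_labels: dict[str, int]
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    constant_rows: list[str]

    def label_vector(self, ids) -> np.ndarray:
        return np.array([self.row_labels[i] for i in ids])


def _zscore_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    constant = sd[:, 0] == 0
    sd[constant] = 1.0
    return (values - mu) / sd, constant


def cluster_expression(mat: ExpressionMatrix, k_rows: int = 2,
                       distance: str = "correlation",
                       linkage: str = "average") -> ClusterResult:
    """Cluster a miRNA x tissue matrix; cut rows into ``k_rows`` groups."""
    if distance not in {"correlation", "euclidean"}:
        raise ClusterError(f"unknown distance {distance!r}")
    if linkage not in {"average", "complete"}:
        raise ClusterError(f"unknown linkage {linkage!r}")
    values = mat.values.to_numpy(dtype=float)
    n_rows, n_cols = values.shape
    if n_rows < 2 or n_cols < 2:
        raise ClusterError("need at least 2 rows and 2 columns")
    if not (1 <= k_rows <= n_rows):
        raise ClusterError(f"k_rows must be in [1, {n_rows}]")

    z, constant = _zscore_rows(values)
    active = np.nonzero(~constant)[0]
    held = np.nonzero(constant)[0]
    if active.size < 2:
        raise ClusterError("fewer than 2 non-constant rows")

    za = z[active]
    row_link = hierarchy.linkage(pdist(za, metric=distance), method=linkage)
    k_active = min(k_rows, active.size)
    labels_active = hierarchy.fcluster(row_link, t=k_active,
                                       criterion="maxclust")

    labels = np.zeros(n_rows, dtype=int)
    labels[active] = labels_active
    if held.size:
        centroids = np.vstack([za[labels_active == c].mean(axis=0)
                               for c in range(1, k_active + 1)])
        for i in held:
            # constant rows z-score to 0; nearest centroid in Euclidean sense
            labels[i] = 1 + int(np.argmin(
                np.linalg.norm(centroids - z[i], axis=1)))

    col_link = hierarchy.linkage(pdist(z.T, metric=distance), method=linkage)
    row_order_idx = [active[i] for i in hierarchy.leaves_list(row_link)]
    row_order_idx += list(held)
    col_order_idx = hierarchy.leaves_list(col_link)

    return ClusterResult(
        row_order=[mat.row_ids[i] for i in row_order_idx],
        col_order=[mat.col_ids[i] for i in col_order_idx],
        row_labels={mat.row_ids[i]: int(labels[i]) for i in range(n_rows)},
        row_linkage=row_link, col_linkage=col_link,
        constant_rows=[mat.row_ids[i] for i in held],
    )


def write_cluster_tsv(mat: ExpressionMatrix, result: ClusterResult,
                      path) -> None:
    """Reordered matrix with a cluster-label column (heatmap export)."""
    df = mat.values.loc[result.row_order, result.col_order].copy()
    df.insert(0, "cluster", [result.row_labels[r] for r in result.row_order])
    df.to_csv(path, sep="\t")
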
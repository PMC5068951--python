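"""Hierarchical clustering of GI profiles.

Mutant sensitivity profiles (GI scores across screens) are clustered by
pairwise average linkage (UPGMA) on the uncentered correlation distance,
the combination popularized by Cluster 3.0 for expression heat maps.
Missing scores are dropped pairwise when computing each distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "Dendrogram",
    "uncentered_corr_distance",
    "pairwise_distances",
    "average_linkage",
    "cluster_gi_profiles",
]

MIN_COMPLETE_POSITIONS = 2


def uncentered_corr_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """1 - uncentered (cosine-type) correlation over pairwise-complete positions.

    d = 1 - sum(x_i y_i) / sqrt(sum(x_i^2) * sum(y_i^2)), in [0, 2].
    Unlike Pearson's r the means are not subtracted, so profiles must agree
    in sign and magnitude, not merely co-vary.  NaN entries are dropped
    pairwise; at least two complete positions are required, and an all-zero
    vector after removal has no defined direction and raises.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("vectors must be 1-D and equally long")
    keep = np.isfinite(xa) & np.isfinite(ya)
    if keep.sum() < MIN_COMPLETE_POSITIONS:
        raise ValueError(
            f"need >= {MIN_COMPLETE_POSITIONS} pairwise-complete positions, got {int(keep.sum())}"
        )
    xa, ya = xa[keep], ya[keep]
    nx = float(xa @ xa)
    ny = float(ya @ ya)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("zero vector after missing-data removal")
    return float(1.0 - (xa @ ya) / np.sqrt(nx * ny))


def pairwise_distances(profiles: pd.DataFrame) -> pd.DataFrame:
    """Symmetric uncentered-correlation distance matrix between matrix rows."""
    ids = list(profiles.index)
    n = len(ids)
    mat = profiles.to_numpy(dtype=float)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = uncentered_corr_distance(mat[i], mat[j])
    return pd.DataFrame(out, index=ids, columns=ids)


@dataclass
class Dendrogram:
    """Average-linkage merge tree over labelled leaves.

    ``merges`` is the scipy linkage matrix: each row merges two nodes at a
    height; heights are non-decreasing (average linkage is monotone).
    """

    merges: np.ndarray
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.merges)
        return [self.labels[i] for i in order]

    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.merges)

        def render(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{self.labels[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{parent_height - node.dist:.6g}"

        inner = f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)})"
        return inner + ";"


def average_linkage(distances: pd.DataFrame) -> Dendrogram:
    """UPGMA (unweighted average linkage) on a precomputed dissimilarity matrix.

    Requires a symmetric matrix with zero diagonal and finite entries;
    missing data must already have been resolved at the distance step.
    """
    mat = distances.to_numpy(dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.all(np.isfinite(mat)):
        raise ValueError("distance matrix contains NaN/inf; resolve missing data first")
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(mat), 0.0, atol=1e-12):
        raise ValueError("distance matrix diagonal must be zero")
    if mat.shape[0] < 2:
        raise ValueError("need at least two leaves")
    condensed = squareform(mat, checks=False)
    merges = hierarchy.linkage(condensed, method="average")
    return Dendrogram(merges=merges, labels=[str(i) for i in distances.index])


def cluster_gi_profiles(
    gi_matrix: pd.DataFrame,
    restrict_to: Sequence[str] | None = None,
) -> tuple[Dendrogram, pd.DataFrame]:
    """Cluster mutants (rows) of a mutants x screens GI matrix.

    Optionally restricted to a hit-list union first.  Returns the
    dendrogram and the matrix reordered to the dendrogram's leaf order,
    ready for heat-map rendering.
    """
    if restrict_to is not None:
        keep = [m for m in gi_matrix.index if m in set(restrict_to)]
        gi_matrix = gi_matrix.loc[keep]
    dist = pairwise_distances(gi_matrix)
    dendro = average_linkage(dist)
    ordered = gi_matrix.loc[dendro.leaf_order]
    return dendro, ordered
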
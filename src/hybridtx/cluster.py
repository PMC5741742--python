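"""Hierarchical clustering of log-transformed expression profiles.

Profiles are compared on log10(FPKM+1) — the display transform of the
study's heatmaps — with correlation distance (1 - Pearson) and average
linkage by default. Clustering can run at the sample level (replicates as
leaves) or, the default, at the line level (replicate means as leaves,
mirroring the eight-leaf tree of the motivating experiment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .expression import line_mean_matrix

__all__ = ["Dendrogram", "log_transform", "cluster_samples", "are_sisters"]


def log_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log10(FPKM + 1); monotone, maps 0 to 0."""
    return np.log10(matrix + 1.0)


@dataclass
class Dendrogram:
    """Agglomerative merge tree over expression profiles."""

    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]
    newick: str

    def cophenetic_height(self) -> float:
        return float(self.linkage[-1, 2])


def _to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Newick string with branch lengths from a scipy linkage matrix."""
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(linkage, labels)
    return str(tree).strip()


def cluster_samples(
    matrix: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    distance: str = "one_minus_pearson",
    linkage: str = "average",
    level: str = "line",
    transformed: bool = False,
) -> Dendrogram:
    """Cluster expression profiles hierarchically.

    ``level="line"`` (requires ``meta``) averages replicates per line first;
    ``level="sample"`` keeps every column as a leaf. Input is raw FPKM
    unless ``transformed`` says the log10(FPKM+1) transform was already
    applied.
    """
    if level == "line":
        if meta is None:
            raise ValueError("line-level clustering needs sample metadata")
        data = line_mean_matrix(matrix, meta)
    elif level == "sample":
        data = matrix
    else:
        raise ValueError("level must be 'line' or 'sample'")
    if data.shape[1] < 2:
        raise ValueError("need at least two profiles to cluster")
    if not transformed:
        data = log_transform(data)

    x = data.to_numpy(dtype=float).T  # profiles x genes
    labels = list(data.columns)
    if distance == "one_minus_pearson":
        flat = x.max(axis=1) == x.min(axis=1)
        if flat.any():
            bad = labels[int(np.flatnonzero(flat)[0])]
            raise ValueError(
                f"profile {bad!r} has constant expression; correlation distance undefined"
            )
        d = pdist(x, metric="correlation")
    elif distance == "euclidean":
        d = pdist(x, metric="euclidean")
    else:
        raise ValueError("distance must be 'one_minus_pearson' or 'euclidean'")
    # clip tiny negative correlation-distance round-off
    d = np.maximum(d, 0.0)
    z = hierarchy.linkage(d, method=linkage)
    return Dendrogram(linkage=z, labels=labels, newick=_to_newick(z, labels))


def are_sisters(dendrogram: Dendrogram, label_a: str, label_b: str) -> bool:
    """True iff the two leaves are merged directly (form a two-leaf clade)."""
    ia = dendrogram.labels.index(label_a)
    ib = dendrogram.labels.index(label_b)
    for row in dendrogram.linkage:
        if {int(row[0]), int(row[1])} == {ia, ib}:
            return True
    return False
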
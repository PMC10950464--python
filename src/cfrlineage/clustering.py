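"""Restarted k-means clustering, log rescaling and barycentric projection.

Clustering and the downstream MST operate on the raw (x1, x2, x3)
coordinates of the snapshot; the natural-log rescaling — which enlarges the
region around the multi-potent state — is used for the |c|^2 lineage
classification statistic and for plotting, and the barycentric coordinates
(y1, y2) project the (logged) data onto the plane perpendicular to the
(1,1,1) diagonal for two-dimensional display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .synthetic import CellDataset

__all__ = [
    "Clustering",
    "log_transform",
    "barycentric_project",
    "kmeans_cluster",
    "cluster_dataset",
]


@dataclass
class Clustering:
    """k-means partition of the cells.

    centroids[j] is the mean of cluster j's members in the clustering space
    (raw coordinates in the standard pipeline); centroids_log[j], when set,
    is the mean of the members' natural-log coordinates — the c_j vectors
    whose squared norms drive lineage classification.  sizes[j] is the
    member count N_j and wcss the within-cluster sum of squared Euclidean
    distances of the selected best-of-restarts run.
    """

    labels: np.ndarray
    k: int
    centroids: np.ndarray
    sizes: np.ndarray
    wcss: float
    centroids_log: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=int)
        if self.sizes.sum() != self.labels.size:
            raise ValueError("cluster sizes must sum to the dataset size")
        if (self.sizes < 1).any():
            raise ValueError("every cluster must contain at least one cell")

    def members(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.labels == j)


def log_transform(data) -> np.ndarray:
    """Componentwise natural log of the expression values.

    Accepts a CellDataset or an (n, 3) array.  Zero or negative values are a
    domain error: basal production keeps simulated levels strictly positive
    (the multiplicative noise cannot cross zero), so hitting this indicates
    a degenerate input rather than a numerical quirk.
    """
    x = data.expression if isinstance(data, CellDataset) else np.asarray(data, dtype=float)
    if np.any(x <= 0):
        raise ValueError(
            "log_transform requires strictly positive expression values "
            "(basal production keeps simulated levels positive; check the input)"
        )
    return np.log(x)


def barycentric_project(points) -> np.ndarray:
    """Project 3-D points onto the plane orthogonal to the (1,1,1) diagonal.

    y1 = (x1 + x2 - 2*x3)/sqrt(6), y2 = (x2 - x1)/sqrt(2).  The diagonal
    maps to the origin and the squared norm y1^2 + y2^2 equals the squared
    distance of the point from the diagonal: (y1, y2) is an orthonormal
    in-plane basis, the projection that maximally separates the three fates.
    """
    x = np.atleast_2d(np.asarray(points, dtype=float))
    y1 = (x[:, 0] + x[:, 1] - 2.0 * x[:, 2]) / np.sqrt(6.0)
    y2 = (x[:, 1] - x[:, 0]) / np.sqrt(2.0)
    out = np.column_stack([y1, y2])
    return out[0] if np.asarray(points).ndim == 1 else out


def kmeans_cluster(
    points,
    k: int,
    n_init: int = 50,
    max_iter: int = 50,
    seed: int = 0,
) -> Clustering:
    """Best-of-``n_init`` restarted k-means under the Euclidean metric.

    Each restart uses k-means++ initialization and up to ``max_iter`` Lloyd
    iterations; the restart with minimal within-cluster sum of squares wins.
    Deterministic given the seed.  Clusters that empty during Lloyd updates
    are re-seeded at the point farthest from its centroid (scikit-learn's
    relocation policy).  Centroids are recomputed from the final labels so
    they are exactly the member means.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must be in [1, {n}]")
    if not 5 <= k <= 40 and k > 1:
        warnings.warn(
            f"k={k} lies outside the well-characterized range 5..40",
            stacklevel=2,
        )
    km = KMeans(
        n_clusters=k,
        n_init=n_init,
        max_iter=max_iter,
        init="k-means++",
        random_state=int(seed) % 2**31,
    ).fit(points)
    labels = km.labels_.astype(int)
    sizes = np.bincount(labels, minlength=k)
    centroids = np.vstack([points[labels == j].mean(axis=0) for j in range(k)])
    wcss = float(((points - centroids[labels]) ** 2).sum())
    return Clustering(labels=labels, k=k, centroids=centroids, sizes=sizes, wcss=wcss)


def cluster_dataset(
    ds: CellDataset,
    k: int,
    n_init: int = 50,
    max_iter: int = 50,
    seed: int = 0,
) -> Clustering:
    """Cluster a snapshot on its raw (x1, x2, x3) coordinates.

    Attaches ``centroids_log`` (per-cluster means of the natural-log
    coordinates) so downstream classification can evaluate |c|^2 without
    re-reading the dataset.
    """
    c = kmeans_cluster(ds.expression, k, n_init=n_init, max_iter=max_iter, seed=seed)
    logx = log_transform(ds)
    c.centroids_log = np.vstack(
        [logx[c.labels == j].mean(axis=0) for j in range(k)]
    )
    return c
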
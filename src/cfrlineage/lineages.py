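"""Cluster-level MST construction, rooting, and lineage extraction.

Clusters are nodes of a complete graph weighted by Euclidean distance
between their centroids (raw-coordinate centroids in the standard
pipeline); the minimum spanning tree of that graph is the backbone of
lineage reconstruction.  A lineage is the unique tree path from the root
cluster (the earliest one) to a leaf.  A simplified project-then-smooth
principal curve is provided for visualization only — it plays no role in
classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .clustering import Clustering
from .synthetic import CellDataset

__all__ = [
    "ClusterTree",
    "Lineage",
    "build_mst",
    "identify_root",
    "extract_lineages",
    "lineage_table",
    "principal_curve",
]


@dataclass
class ClusterTree:
    """Rooted (or not yet rooted) minimum spanning tree over cluster centroids."""

    graph: nx.Graph
    root: int | None = None

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[int, int]]:
        return [tuple(sorted(e)) for e in self.graph.edges]

    def total_weight(self) -> float:
        return float(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))


@dataclass
class Lineage:
    """Ordered cluster path from the root to one terminal (leaf) cluster."""

    path: list[int]
    length: int
    elapsed_time: float | None = None
    terminal_cnorm_sq: float | None = None
    ltype: str | None = None
    ambiguous: bool = False

    @property
    def terminal(self) -> int:
        return self.path[-1]


def build_mst(centroids) -> ClusterTree:
    """Minimum spanning tree under Euclidean distance between centroids.

    Edges are fed to Kruskal in lexicographic (min-id, max-id) order so that
    equal-weight ties resolve deterministically.  Duplicate centroids are an
    error (they would make the clustering itself suspect) rather than being
    silently perturbed.
    """
    c = np.asarray(centroids, dtype=float)
    k = c.shape[0]
    if k < 2:
        raise ValueError("build_mst needs at least 2 clusters")
    G = nx.Graph()
    G.add_nodes_from(range(k))
    for i in range(k):
        for j in range(i + 1, k):
            w = float(np.linalg.norm(c[i] - c[j]))
            if w == 0.0:
                raise ValueError(f"clusters {i} and {j} have identical centroids")
            G.add_edge(i, j, weight=w)
    mst = nx.minimum_spanning_tree(G, algorithm="kruskal")
    return ClusterTree(graph=mst)


def identify_root(clustering: Clustering, ds: CellDataset) -> int:
    """Cluster with the minimal mean sample time of its members.

    In this synthetic setting the earliest cells sit near the initial
    condition on the (1,1,1) axis, so the earliest-time cluster is the
    multi-potent root.  Ties (measure-zero) go to the lowest cluster index.
    """
    times = ds.times
    mean_t = np.array(
        [times[clustering.labels == j].mean() for j in range(clustering.k)]
    )
    return int(np.argmin(mean_t))


def extract_lineages(tree: ClusterTree) -> list[Lineage]:
    """One lineage per leaf of the rooted MST (the root never terminates one).

    Each path is the unique tree path from the root to a degree-1 node; the
    root is excluded from the leaf set even when it has degree 1, since
    lineages are directed away from the multi-potent state.
    """
    if tree.root is None:
        raise ValueError("tree must be rooted before extracting lineages")
    G = tree.graph
    if G.number_of_nodes() == 1:
        warnings.warn("single-cluster tree has no lineages", stacklevel=2)
        return []
    leaves = [n for n in G.nodes if G.degree(n) == 1 and n != tree.root]
    lineages = []
    for leaf in sorted(leaves):
        path = nx.shortest_path(G, tree.root, leaf)
        lineages.append(Lineage(path=list(path), length=len(path)))
    return lineages


def lineage_table(
    tree: ClusterTree, clustering: Clustering, ds: CellDataset
) -> list[Lineage]:
    """Extract lineages and fill in their summary statistics.

    elapsed_time is the difference of mean sample times between the terminal
    and root clusters (the synthetic data carries true simulation time, so no
    pseudotime estimator is needed); terminal_cnorm_sq is the squared norm of
    the terminal cluster's log-centroid, the quantity used for type A/B
    classification.
    """
    lineages = extract_lineages(tree)
    times = ds.times
    mean_t = np.array(
        [times[clustering.labels == j].mean() for j in range(clustering.k)]
    )
    if clustering.centroids_log is not None:
        centroids_log = clustering.centroids_log
    else:
        logx = np.log(ds.expression)
        centroids_log = np.vstack(
            [logx[clustering.labels == j].mean(axis=0) for j in range(clustering.k)]
        )
    for lin in lineages:
        lin.elapsed_time = float(mean_t[lin.terminal] - mean_t[tree.root])
        lin.terminal_cnorm_sq = float(np.sum(centroids_log[lin.terminal] ** 2))
    return lineages


def _project_to_polyline(points: np.ndarray, poly: np.ndarray):
    """Arclength position and squared distance of each point's nearest foot
    on the polyline."""
    seg = np.diff(poly, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    best_s = np.zeros(points.shape[0])
    best_d2 = np.full(points.shape[0], np.inf)
    for i in range(seg.shape[0]):
        if seg_len[i] == 0:
            continue
        v = seg[i]
        t = np.clip((points - poly[i]) @ v / (seg_len[i] ** 2), 0.0, 1.0)
        foot = poly[i] + t[:, None] * v
        d2 = ((points - foot) ** 2).sum(axis=1)
        better = d2 < best_d2
        best_d2[better] = d2[better]
        best_s[better] = cum[i] + t[better] * seg_len[i]
    return best_s, best_d2


def principal_curve(
    points,
    initial_path,
    tol: float = 1e-4,
    max_iter: int = 50,
    span: float = 0.1,
):
    """Simplified Hastie--Stuetzle principal curve for plotting lineages.

    Alternates (i) orthogonal projection of the points onto the current
    polyline, giving arclength positions, and (ii) smoothing each coordinate
    against arclength with a local running mean of width ``span`` (fraction
    of the points).  Iteration stops when the mean squared projection
    distance changes by less than ``tol``, when it would increase (the last
    improving iterate is returned), or after ``max_iter`` sweeps.

    Returns (curve, projections): the smoothed polyline and each point's
    arclength along it (a pseudotime for display purposes only).
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 10:
        raise ValueError("principal_curve needs at least 10 points")
    poly = np.asarray(initial_path, dtype=float)
    window = max(3, int(span * points.shape[0]))

    s, d2 = _project_to_polyline(points, poly)
    err = float(d2.mean())
    for _ in range(max_iter):
        order = np.argsort(s, kind="stable")
        sorted_pts = points[order]
        kernel = np.ones(window) / window
        smooth = np.column_stack(
            [
                np.convolve(
                    np.pad(sorted_pts[:, c], (window // 2, window - 1 - window // 2), mode="edge"),
                    kernel,
                    mode="valid",
                )
                for c in range(points.shape[1])
            ]
        )
        # drop consecutive duplicates so segments have positive length
        keep = np.concatenate([[True], np.linalg.norm(np.diff(smooth, axis=0), axis=1) > 0])
        new_poly = smooth[keep]
        if new_poly.shape[0] < 2:
            warnings.warn("principal curve collapsed; returning last iterate", stacklevel=2)
            break
        new_s, new_d2 = _project_to_polyline(points, new_poly)
        new_err = float(new_d2.mean())
        if new_err > err:
            break  # keep the last improving iterate
        poly, s = new_poly, new_s
        if err - new_err < tol:
            err = new_err
            break
        err = new_err
    else:
        warnings.warn("principal curve did not converge; returning last iterate", stacklevel=2)
    return poly, s
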
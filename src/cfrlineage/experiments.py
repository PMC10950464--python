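"""Replicated end-to-end realizations over (alpha, sigma, k) grids.

One *realization* is the full pipeline: SDE simulation -> fate-balanced
1200-cell snapshot -> best-of-50 k-means on the raw coordinates -> Euclidean
centroid MST -> earliest-time root -> lineage extraction -> type A/B
classification of terminal log-centroid norms.  Sweeps replicate
realizations and tabulate the distribution of type A and type B counts per
grid cell, mirroring the stacked-bar and heatmap summaries of the study
design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import ClassifierConfig, classify_lineages, count_types
from .clustering import cluster_dataset
from .dynamics import CFRParams, SignalParams, SimSettings
from .lineages import build_mst, identify_root, lineage_table
from .synthetic import CellDataset, generate_dataset

__all__ = [
    "RealizationResult",
    "SweepTable",
    "run_realization",
    "analyze_dataset",
    "sweep",
]


@dataclass
class RealizationResult:
    alpha: float
    sigma: float
    k: int
    seed: int
    n_a: int
    n_b: int
    lineages: list = field(default_factory=list, repr=False)


@dataclass
class SweepTable:
    """Distributions of lineage-type counts over a (alpha, k) grid.

    dist_a / dist_b map (alpha, k) to {count: proportion}; mean_b is a
    (len(alphas), len(ks)) matrix of the average type-B count, the heatmap
    quantity.  Proportions in each cell sum to 1.
    """

    alphas: list
    sigma: float
    ks: list
    n_real: int
    dist_a: dict
    dist_b: dict
    mean_b: np.ndarray
    results: pd.DataFrame

    def proportion(self, alpha: float, k: int, *, ltype: str, count: int) -> float:
        d = (self.dist_a if ltype == "A" else self.dist_b)[(alpha, k)]
        return d.get(count, 0.0)


def analyze_dataset(
    ds: CellDataset,
    k: int,
    seed: int = 0,
    cfg: ClassifierConfig = ClassifierConfig(),
):
    """Cluster -> MST -> root -> lineages -> classify on an existing dataset.

    Returns (n_a, n_b, lineages).  Errors from any stage propagate with the
    stage named.
    """
    stage = "kmeans"
    try:
        clustering = cluster_dataset(ds, k=k, seed=seed)
        stage = "mst"
        tree = build_mst(clustering.centroids)
        stage = "root"
        tree.root = identify_root(clustering, ds)
        stage = "lineages"
        lineages = lineage_table(tree, clustering, ds)
        stage = "classify"
        classify_lineages(lineages, cfg)
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return count_types(lineages, cfg) + (lineages,)


def run_realization(
    alpha: float,
    sigma: float,
    k: int,
    seed: int,
    cfg: ClassifierConfig = ClassifierConfig(),
    n_per: int = 400,
) -> RealizationResult:
    """One full pipeline run under a single master seed.

    The master seed is split into independent streams for the SDE path, the
    cell sampling, and the k-means restarts, so any realization of any sweep
    cell can be re-run in isolation.
    """
    ss = np.random.SeedSequence(seed)
    data_seed, km_seed = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))
    ds = generate_dataset(
        params=CFRParams(alpha=alpha),
        settings=SimSettings(sigma=sigma),
        n_per=n_per,
        seed=data_seed,
    )
    n_a, n_b, lineages = analyze_dataset(ds, k=k, seed=km_seed, cfg=cfg)
    return RealizationResult(
        alpha=alpha, sigma=sigma, k=k, seed=seed, n_a=n_a, n_b=n_b, lineages=lineages
    )


def sweep(
    alphas,
    sigma: float,
    ks,
    n_real: int = 500,
    master_seed: int = 0,
    cfg: ClassifierConfig = ClassifierConfig(),
    share_data_across_k: bool = True,
) -> SweepTable:
    """Replicated sweep over an (alpha, k) grid at fixed noise level.

    Each alpha column gets its own independently generated datasets; within
    a column the same ``n_real`` datasets are re-analysed at every k (so
    results within a column are correlated by construction, as in the
    stacked-bar and heatmap protocols).  Set ``share_data_across_k=False``
    to regenerate data per (alpha, k) cell instead; mean trends agree within
    Monte-Carlo error.
    """
    if n_real < 1:
        raise ValueError("n_real must be >= 1")
    alphas = list(alphas)
    ks = list(ks)
    ss = np.random.SeedSequence(master_seed)
    rows = []
    for alpha in alphas:
        col_ss = ss.spawn(1)[0]
        if share_data_across_k:
            rep_seeds = col_ss.spawn(n_real)
            datasets = []
            km_seeds = []
            for child in rep_seeds:
                d_seed, k_seed = (
                    int(c.generate_state(1)[0] % 2**31) for c in child.spawn(2)
                )
                datasets.append(
                    generate_dataset(
                        params=CFRParams(alpha=alpha),
                        settings=SimSettings(sigma=sigma),
                        seed=d_seed,
                    )
                )
                km_seeds.append(k_seed)
            for k in ks:
                for r in range(n_real):
                    n_a, n_b, _ = analyze_dataset(
                        datasets[r], k=k, seed=km_seeds[r], cfg=cfg
                    )
                    rows.append((alpha, sigma, k, r, n_a, n_b))
        else:
            for k in ks:
                cell_ss = col_ss.spawn(1)[0]
                for r, child in enumerate(cell_ss.spawn(n_real)):
                    seed = int(child.generate_state(1)[0] % 2**31)
                    res = run_realization(alpha, sigma, k, seed, cfg=cfg)
                    rows.append((alpha, sigma, k, r, res.n_a, res.n_b))

    df = pd.DataFrame(rows, columns=["alpha", "sigma", "k", "rep", "n_a", "n_b"])
    dist_a, dist_b = {}, {}
    mean_b = np.zeros((len(alphas), len(ks)))
    for ai, alpha in enumerate(alphas):
        for ki, k in enumerate(ks):
            cell = df[(df.alpha == alpha) & (df.k == k)]
            dist_a[(alpha, k)] = cell.n_a.value_counts(normalize=True).to_dict()
            dist_b[(alpha, k)] = cell.n_b.value_counts(normalize=True).to_dict()
            mean_b[ai, ki] = cell.n_b.mean()
    return SweepTable(
        alphas=alphas,
        sigma=sigma,
        ks=ks,
        n_real=n_real,
        dist_a=dist_a,
        dist_b=dist_b,
        mean_b=mean_b,
        results=df,
    )
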
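"""Synthetic snapshot datasets emulating scRNA-seq input.

SDE sample paths are turned into a fate-balanced population: the cyclic
symmetry of the cross-repressilator means the two cyclic coordinate
permutations of a trajectory are themselves valid trajectories terminating
at the other two fates.  The default generator simulates 400 independent
paths, permutes each into a fate triplet and observes every copy at one
uniformly drawn time; a single-path mode instead samples 400 stored points
from each copy of one permuted path.  Either way the result is the
1200-cell snapshot that the reconstruction pipeline consumes, exported as a
``t,x1,x2,x3`` CSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import (
    CFRParams,
    SignalParams,
    SimSettings,
    Trajectory,
    simulate_sde,
    simulate_sde_ensemble,
)

__all__ = [
    "CellDataset",
    "make_fate_triplet",
    "sample_cells",
    "write_dataset",
    "read_dataset",
    "generate_dataset",
]

_COLUMNS = ["t", "x1", "x2", "x3"]


@dataclass
class CellDataset:
    """Fate-balanced collection of (t, x1, x2, x3) snapshot records."""

    records: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.records.columns) != _COLUMNS:
            raise ValueError(f"records must have columns {_COLUMNS}")
        if (self.records[["x1", "x2", "x3"]].to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def times(self) -> np.ndarray:
        return self.records["t"].to_numpy()

    @property
    def expression(self) -> np.ndarray:
        """(n, 3) array of raw TF levels."""
        return self.records[["x1", "x2", "x3"]].to_numpy()


def make_fate_triplet(traj: Trajectory) -> tuple[Trajectory, Trajectory, Trajectory]:
    """Original trajectory plus its two cyclic coordinate permutations.

    Each copy terminates at a different one of the three fates.  If the
    source trajectory has no clearly dominant terminal coordinate (an
    atypical run that spent unusually long spiralling) a warning is raised
    but the triplet is still returned.
    """
    terminal = traj.states[-1]
    order = np.argsort(terminal)[::-1]
    if terminal[order[0]] <= 10.0 * terminal[order[1]]:
        warnings.warn(
            "trajectory has no dominant terminal coordinate; fates of the "
            "permuted copies may be ambiguous",
            stacklevel=2,
        )
    perms = []
    for shift in range(3):
        states = np.roll(traj.states, shift, axis=1)
        perms.append(Trajectory(traj.times.copy(), states))
    return tuple(perms)


def sample_cells(
    triplet: tuple[Trajectory, Trajectory, Trajectory],
    n_per: int = 400,
    seed: int | np.random.Generator = 0,
) -> CellDataset:
    """Sample ``n_per`` stored time points from each trajectory of the triplet.

    Sampling is uniform over the stored grid, without replacement, and
    independent across the three copies, so the three fates contribute
    exactly n_per cells each (3 * 400 = 1200 by default).  Source times are
    retained in the records.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frames = []
    for traj in triplet:
        if n_per > len(traj):
            raise ValueError(
                f"n_per={n_per} exceeds the {len(traj)} stored points per trajectory"
            )
        idx = np.sort(rng.choice(len(traj), size=n_per, replace=False))
        frames.append(
            pd.DataFrame(
                {
                    "t": traj.times[idx],
                    "x1": traj.states[idx, 0],
                    "x2": traj.states[idx, 1],
                    "x3": traj.states[idx, 2],
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)
    return CellDataset(records, provenance={"n_per": n_per})


def write_dataset(ds: CellDataset, path) -> None:
    """Export as CSV with header ``t,x1,x2,x3`` at full float precision."""
    ds.records.to_csv(path, index=False, float_format="%.17g")


def read_dataset(path) -> CellDataset:
    """Read a dataset CSV, validating header and values.

    Malformed headers or non-numeric fields raise a ValueError naming the
    offending row/column; negative expression values are rejected.
    """
    df = pd.read_csv(path)
    if list(df.columns) != _COLUMNS:
        raise ValueError(f"expected header {','.join(_COLUMNS)}, got {list(df.columns)}")
    for col in _COLUMNS:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if df[col].isna().any() or bad.any():
            row = int(np.argmax((df[col].isna() | bad).to_numpy()))
            raise ValueError(f"non-numeric or missing value at row {row}, column '{col}'")
        df[col] = df[col].astype(float)
    return CellDataset(df)


def generate_dataset(
    params: CFRParams | None = None,
    signal: SignalParams | None = None,
    settings: SimSettings | None = None,
    n_per: int = 400,
    seed: int = 0,
    mode: str = "ensemble",
) -> CellDataset:
    """End-to-end fate-balanced snapshot generator.

    ``mode="ensemble"`` (default): simulate ``n_per`` independent SDE sample
    paths, take the three cyclic coordinate permutations of each, and
    observe every path copy at one uniformly drawn stored time — each cell
    is a different simulated cell, so within-fate scatter reflects genuine
    path-to-path variability.  ``mode="single_path"``: one SDE realization
    is permuted into a fate triplet and ``n_per`` stored points are sampled
    from each copy (cells of a fate then share one underlying path).  At
    sigma = 0 all ensemble paths coincide, so a single path is simulated and
    observation times are drawn with replacement.
    """
    if mode not in ("ensemble", "single_path"):
        raise ValueError("mode must be 'ensemble' or 'single_path'")
    params = params or CFRParams()
    signal = signal or SignalParams()
    settings = settings or SimSettings()
    ss = np.random.SeedSequence(seed)
    sde_seed, sample_seed = ss.spawn(2)
    sim = SimSettings(
        t_start=settings.t_start,
        t_end=settings.t_end,
        dt=settings.dt,
        sigma=settings.sigma,
        seed=int(sde_seed.generate_state(1)[0] % 2**31),
        x0=settings.x0,
    )
    rng = np.random.default_rng(sample_seed)

    if mode == "single_path":
        traj = simulate_sde(params, signal, sim)
        ds = sample_cells(make_fate_triplet(traj), n_per=n_per, seed=rng)
    else:
        n_paths = 1 if settings.sigma == 0 else n_per
        times, states = simulate_sde_ensemble(params, signal, sim, n_paths=n_paths)
        frames = []
        for shift in range(3):
            idx = rng.integers(0, times.size, size=n_per)
            path_idx = np.zeros(n_per, dtype=int) if n_paths == 1 else np.arange(n_per)
            pts = np.roll(states[idx, path_idx, :], shift, axis=1)
            frames.append(
                pd.DataFrame(
                    {"t": times[idx], "x1": pts[:, 0], "x2": pts[:, 1], "x3": pts[:, 2]}
                )
            )
        ds = CellDataset(pd.concat(frames, ignore_index=True))

    ds.provenance = {
        "alpha": params.alpha,
        "beta": params.beta,
        "sigma": settings.sigma,
        "n_per": n_per,
        "seed": seed,
        "mode": mode,
    }
    return ds
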
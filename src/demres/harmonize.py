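"""Common time grid, interpolation, covariate alignment and epoch summaries.

Piecewise Ne reconstructions from different populations and bootstrap
replicates live on different time discretizations.  To compare them we

1. take the midpoint of each segment's time boundaries,
2. build a common grid of 100 logarithmically spaced points between 1 year
   and the maximum reconstructed time rounded to the nearest million years,
3. linearly interpolate each trajectory onto that grid, keeping grid points
   outside a trajectory's range as missing (NaN), and
4. summarise Ne inside a climatic epoch by the weighted harmonic mean with
   segment-overlap durations as weights (drift compounds via 1/Ne, so the
   harmonic mean is the natural epoch average).

The sea-level covariate is aligned onto the same grid by linear
interpolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .smc_io import NeTrajectory

__all__ = [
    "Epoch",
    "DEFAULT_EPOCHS",
    "CommonGrid",
    "TrajectoryEnsemble",
    "midpoint_times",
    "build_common_grid",
    "interpolate_to_grid",
    "weighted_harmonic_mean_ne",
    "harmonic_mean_table",
    "align_covariate",
    "standardize",
    "build_ensemble",
]

N_GRID = 100


@dataclass(frozen=True)
class Epoch:
    """A named interval of years before present, ``t_start < t_end``."""

    name: str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("epoch must satisfy t_start < t_end")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


#: Two windows of pronounced sea-level fluctuation and the post-glacial rise.
DEFAULT_EPOCHS = (
    Epoch("fluctuation_350_150ka", 150_000.0, 350_000.0),
    Epoch("fluctuation_120_15ka", 15_000.0, 120_000.0),
    Epoch("rise_15_0ka", 0.0, 15_000.0),
)


@dataclass(frozen=True)
class CommonGrid:
    """Exactly 100 log-spaced times in years, from 1 to a rounded maximum."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if len(pts) != N_GRID:
            raise ValueError(f"grid must have {N_GRID} points")
        if not np.all(np.diff(pts) > 0):
            raise ValueError("grid must be strictly increasing")
        if pts[0] != 1.0:
            raise ValueError("grid must start at 1 year")

    def __len__(self) -> int:
        return N_GRID

    @property
    def max_time(self) -> float:
        return float(self.points[-1])


def build_common_grid(max_time: float) -> CommonGrid:
    """100 log-spaced points from 1 to ``max_time`` rounded to nearest 1e6.

    Rounding is half-up with a floor of one million years so the grid always
    spans at least the last glacial cycles.
    """
    if not max_time > 1:
        raise ValueError("max_time must exceed 1 year")
    m = max(1.0, math.floor(max_time / 1e6 + 0.5)) * 1e6
    i = np.arange(N_GRID)
    return CommonGrid(points=10 ** (np.log10(m) * i / (N_GRID - 1)))


def midpoint_times(traj: NeTrajectory) -> tuple[np.ndarray, np.ndarray]:
    """Segment midpoints ``(t_left + t_right) / 2`` with their Ne values.

    Segments with an infinite right boundary carry no defined midpoint and
    are dropped.
    """
    finite = np.isfinite(traj.t_right)
    if not finite.any():
        raise ValueError("trajectory has no finite segment")
    t_mid = (traj.t_left[finite] + traj.t_right[finite]) / 2.0
    return t_mid, traj.ne[finite].copy()


def interpolate_to_grid(
    t_mid: np.ndarray, ne: np.ndarray, grid: CommonGrid
) -> np.ndarray:
    """Linear interpolation of Ne at grid times; NaN outside coverage.

    Interpolation is linear in raw time and raw Ne.  Midpoints with masked
    (NaN) Ne are excluded before interpolation, so a masked interior value
    is bridged by its neighbours while masked edges shrink the covered
    range.
    """
    t_mid = np.asarray(t_mid, dtype=float)
    ne = np.asarray(ne, dtype=float)
    keep = ~np.isnan(ne)
    t_mid, ne = t_mid[keep], ne[keep]
    if len(t_mid) < 2:
        raise ValueError("need at least 2 midpoints to interpolate")
    order = np.argsort(t_mid)
    t_mid, ne = t_mid[order], ne[order]
    out = np.interp(grid.points, t_mid, ne)
    out[(grid.points < t_mid[0]) | (grid.points > t_mid[-1])] = np.nan
    return out


def weighted_harmonic_mean_ne(traj: NeTrajectory, epoch: Epoch) -> float:
    """Epoch summary ``H = sum(w) / sum(w / Ne)``, weights = overlap years.

    Operates on the original piecewise segments (their durations are the
    weights), not on the interpolated grid.  Masked segments contribute no
    weight.  This equals the continuous-time harmonic mean
    ``1 / mean(1/Ne(t))`` exactly for piecewise-constant Ne.
    """
    lo = np.maximum(traj.t_left, epoch.t_start)
    hi = np.minimum(traj.t_right, epoch.t_end)
    w = np.clip(hi - lo, 0.0, None)
    w[np.isnan(traj.ne)] = 0.0
    total = w.sum()
    if total <= 0:
        raise ValueError(
            f"trajectory {traj.key} has no non-missing overlap with epoch {epoch.name}"
        )
    used = w > 0
    return float(total / np.sum(w[used] / traj.ne[used]))


def align_covariate(
    ages: np.ndarray, levels: np.ndarray, grid: CommonGrid
) -> np.ndarray:
    """Linear interpolation of an environmental series at grid times.

    Grid times outside the series' age span are NaN (no extrapolation).
    """
    ages = np.asarray(ages, dtype=float)
    levels = np.asarray(levels, dtype=float)
    out = np.interp(grid.points, ages, levels)
    out[(grid.points < ages[0]) | (grid.points > ages[-1])] = np.nan
    return out


def standardize(values: np.ndarray) -> np.ndarray:
    """Z-scores ``(x - mean) / sd`` (sample sd, ddof=1); NaN propagates."""
    x = np.asarray(values, dtype=float)
    finite = x[~np.isnan(x)]
    if len(finite) < 2:
        raise ValueError("need at least 2 non-missing values to standardize")
    sd = finite.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize values with zero spread")
    return (x - finite.mean()) / sd


@dataclass
class TrajectoryEnsemble:
    """Trajectories interpolated onto a shared grid, with group labels.

    ``values`` is (n_trajectories, 100) with NaN where a trajectory does not
    cover a grid point; ``meta`` has one row per trajectory with columns
    species, population, replicate and host_category; ``trajectories`` keeps
    the original piecewise objects (same order) for segment-based epoch
    summaries.
    """

    grid: CommonGrid
    values: np.ndarray
    meta: pd.DataFrame
    trajectories: list[NeTrajectory]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.meta), len(self.grid)):
            raise ValueError("values shape must be (n_trajectories, n_grid)")
        present = self.values[~np.isnan(self.values)]
        if not np.all(present > 0):
            raise ValueError("Ne must be positive where present")

    def __len__(self) -> int:
        return len(self.meta)

    def subset(self, row_mask: np.ndarray) -> "TrajectoryEnsemble":
        idx = np.flatnonzero(row_mask)
        return TrajectoryEnsemble(
            grid=self.grid,
            values=self.values[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
            trajectories=[self.trajectories[i] for i in idx],
        )

    def epoch_mask(self, epoch: Epoch) -> np.ndarray:
        """Boolean mask over grid points falling inside the epoch."""
        return (self.grid.points >= epoch.t_start) & (self.grid.points <= epoch.t_end)

    def to_long(self, sea_level: np.ndarray | None = None) -> pd.DataFrame:
        """Tidy long table (species, population, replicate, time, Ne[, sea])."""
        n, g = self.values.shape
        df = self.meta.loc[self.meta.index.repeat(g)].reset_index(drop=True)
        df["time"] = np.tile(self.grid.points, n)
        df["Ne"] = self.values.ravel()
        if sea_level is not None:
            df["sea_level"] = np.tile(np.asarray(sea_level, dtype=float), n)
        return df


def build_ensemble(
    trajectories: list[NeTrajectory],
    host_of_species: dict[str, str],
    grid: CommonGrid | None = None,
) -> TrajectoryEnsemble:
    """Interpolate trajectories onto a shared grid.

    If no grid is given, one is built from the largest finite time boundary
    across all trajectories.
    """
    if not trajectories:
        raise ValueError("no trajectories supplied")
    if grid is None:
        max_t = max(
            float(np.max(t.t_right[np.isfinite(t.t_right)])) for t in trajectories
        )
        grid = build_common_grid(max_t)
    rows = []
    values = np.empty((len(trajectories), len(grid)))
    for i, traj in enumerate(trajectories):
        t_mid, ne = midpoint_times(traj)
        values[i] = interpolate_to_grid(t_mid, ne, grid)
        rows.append(
            {
                "species": traj.species,
                "population": traj.population,
                "replicate": traj.replicate_id,
                "host_category": host_of_species[traj.species],
            }
        )
    return TrajectoryEnsemble(
        grid=grid,
        values=values,
        meta=pd.DataFrame(rows),
        trajectories=list(trajectories),
    )


def harmonic_mean_table(
    ensemble: TrajectoryEnsemble, epochs: tuple[Epoch, ...] = DEFAULT_EPOCHS
) -> pd.DataFrame:
    """Weighted harmonic-mean Ne per trajectory per epoch (long format).

    Trajectories with no non-missing overlap with an epoch are skipped.
    """
    rows = []
    for i, traj in enumerate(ensemble.trajectories):
        for epoch in epochs:
            try:
                h = weighted_harmonic_mean_ne(traj, epoch)
            except ValueError:
                continue
            rec = ensemble.meta.iloc[i].to_dict()
            rec.update(epoch=epoch.name, harmonic_mean_ne=h)
            rows.append(rec)
    return pd.DataFrame(rows)
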
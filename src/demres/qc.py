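"""Quantile-based reliability filters for bootstrap Ne reconstructions.

Two filters are applied to SMC bootstrap output before any comparative
analysis:

* **outlier replicates** — within a species and a time epoch, any replicate
  containing at least one Ne value strictly above the 97.5% quantile of all
  Ne values pooled across that species' replicates (and, by default, its
  populations) in the epoch is removed entirely for its population.  Such
  spikes typically arise from bootstrap draws containing hybrids or
  migrants.
* **edge trimming** — within a single replicate, Ne values strictly above
  the 95% quantile of that replicate's own values are masked; implausibly
  large estimates concentrate at the time edges where coalescent
  information runs out.

Quantiles interpolate linearly between order statistics
(``h = (n - 1) * q``), so thresholds are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .harmonize import Epoch, TrajectoryEnsemble, interpolate_to_grid, midpoint_times

__all__ = [
    "QCReport",
    "quantile_threshold",
    "flag_outlier_replicates",
    "trim_extreme_values",
    "apply_trim",
    "apply_exclusions",
]


@dataclass
class QCReport:
    """Filter outcomes: whole replicates removed and single values masked."""

    removed_replicates: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["species", "population", "replicate", "trigger_value", "threshold"]
        )
    )
    masked_points: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["species", "population", "replicate", "time", "Ne", "threshold"]
        )
    )


def quantile_threshold(values: np.ndarray, q: float) -> float:
    """q-quantile with linear interpolation between order statistics."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) == 0:
        raise ValueError("no non-missing values for quantile")
    return float(np.quantile(values, q))


def flag_outlier_replicates(
    ensemble: TrajectoryEnsemble,
    epoch: Epoch,
    q: float = 0.975,
    pool: str = "species",
) -> tuple[TrajectoryEnsemble, QCReport]:
    """Remove replicates whose in-epoch Ne exceeds the pooled q-quantile.

    ``pool`` selects whether the quantile pools Ne values across all of a
    species' populations (default) or is computed per population.  Removal
    is per (species, population, replicate): one bad value discards the
    whole replicate for that population.  The comparison is strict, so when
    all values are identical nothing is removed.
    """
    if pool not in ("species", "population"):
        raise ValueError("pool must be 'species' or 'population'")
    pmask = ensemble.epoch_mask(epoch)
    if not pmask.any():
        raise ValueError(f"no grid points inside epoch {epoch.name}")
    in_epoch = ensemble.values[:, pmask]

    group_cols = ["species"] if pool == "species" else ["species", "population"]
    keys = ensemble.meta[group_cols].agg(tuple, axis=1)
    keep = np.ones(len(ensemble), dtype=bool)
    removed = []
    for key, idx in keys.groupby(keys).groups.items():
        idx = np.asarray(idx)
        pool_values = in_epoch[idx]
        if np.all(np.isnan(pool_values)):
            continue
        thr = quantile_threshold(pool_values.ravel(), q)
        for i in idx:
            row = in_epoch[i]
            if np.any(row[~np.isnan(row)] > thr):
                keep[i] = False
                removed.append(
                    {
                        "species": ensemble.meta.at[i, "species"],
                        "population": ensemble.meta.at[i, "population"],
                        "replicate": ensemble.meta.at[i, "replicate"],
                        "trigger_value": float(np.nanmax(row)),
                        "threshold": thr,
                    }
                )
    report = QCReport()
    if removed:
        report.removed_replicates = pd.DataFrame(removed)
    return ensemble.subset(keep), report


def trim_extreme_values(
    values: np.ndarray, q: float = 0.95, mode: str = "literal"
) -> tuple[np.ndarray, float, np.ndarray]:
    """Mask values strictly above the series' own q-quantile.

    Returns ``(masked_values, threshold, masked_indices)``.  ``mode
    'literal'`` masks every exceeding value; ``'edges'`` masks only leading
    and trailing runs of exceeding values, leaving interior spikes alone.
    """
    if mode not in ("literal", "edges"):
        raise ValueError("mode must be 'literal' or 'edges'")
    x = np.asarray(values, dtype=float).copy()
    finite = ~np.isnan(x)
    if finite.sum() < 3:
        raise ValueError("need at least 3 non-missing values to trim")
    thr = quantile_threshold(x, q)
    above = finite & (x > thr)
    if mode == "edges" and above.any():
        run = np.zeros_like(above)
        for i in range(len(x)):  # leading run
            if not finite[i]:
                continue
            if above[i]:
                run[i] = True
            else:
                break
        for i in range(len(x) - 1, -1, -1):  # trailing run
            if not finite[i]:
                continue
            if above[i]:
                run[i] = True
            else:
                break
        above = run
    idx = np.flatnonzero(above)
    x[idx] = np.nan
    return x, thr, idx


def apply_trim(
    ensemble: TrajectoryEnsemble, q: float = 0.95, mode: str = "literal"
) -> tuple[TrajectoryEnsemble, QCReport]:
    """Trim each replicate's trajectory and re-interpolate onto the grid.

    The threshold is computed from each replicate's own segment-level Ne
    values; masked segments then carry no weight in harmonic means and are
    excluded from interpolation.  A replicate left with fewer than two
    usable midpoints becomes all-missing on the grid.
    """
    masked_rows = []
    new_trajs = []
    values = np.full_like(ensemble.values, np.nan)
    for i, traj in enumerate(ensemble.trajectories):
        try:
            masked, thr, idx = trim_extreme_values(traj.ne, q=q, mode=mode)
        except ValueError:
            new_trajs.append(traj)
            values[i] = ensemble.values[i]
            continue
        new_traj = traj.with_ne(masked)
        new_trajs.append(new_traj)
        for j in idx:
            masked_rows.append(
                {
                    "species": traj.species,
                    "population": traj.population,
                    "replicate": traj.replicate_id,
                    "time": float((traj.t_left[j] + traj.t_right[j]) / 2.0),
                    "Ne": float(traj.ne[j]),
                    "threshold": thr,
                }
            )
        try:
            t_mid, ne = midpoint_times(new_traj)
            values[i] = interpolate_to_grid(t_mid, ne, ensemble.grid)
        except ValueError:
            pass  # stays all-NaN
    report = QCReport()
    if masked_rows:
        report.masked_points = pd.DataFrame(masked_rows)
    out = TrajectoryEnsemble(
        grid=ensemble.grid,
        values=values,
        meta=ensemble.meta.copy(),
        trajectories=new_trajs,
    )
    return out, report


def apply_exclusions(
    ensemble: TrajectoryEnsemble,
    exclusions: list[tuple[str, str, str]],
) -> TrajectoryEnsemble:
    """Drop curated (species, population, replicate) triples; '*' wildcards.

    Dataset-specific removals (for example, whole bootstrap sets known to
    contain hybrids) are configured here rather than hard-coded.
    """
    keep = np.ones(len(ensemble), dtype=bool)
    for sp, pop, rep in exclusions:
        m = np.ones(len(ensemble), dtype=bool)
        if sp != "*":
            m &= (ensemble.meta["species"] == sp).to_numpy()
        if pop != "*":
            m &= (ensemble.meta["population"] == pop).to_numpy()
        if rep != "*":
            m &= (ensemble.meta["replicate"] == rep).to_numpy()
        keep &= ~m
    return ensemble.subset(keep)
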
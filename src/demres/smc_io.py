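"""Read, write and rescale SMC-style coalescence-rate tables.

Sequentially-Markovian-coalescent tools (MSMC2 and relatives) emit
piecewise-constant coalescence rates ``lambda`` on scaled (dimensionless)
time segments.  This module parses that dialect, converts between scaled
units and real years / absolute effective population size (Ne), and reads
the combined cross-population three-rate tables used for split-time
estimation.

Unit conventions
----------------
* scaled time ``t`` maps to real time ``t / mu * gen_time`` years before
  present (present = 0);
* scaled rate ``lambda`` maps to ``Ne = 1 / (2 * mu * lambda)`` diploid
  individuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ScalingConstants",
    "ScaledRateSeries",
    "NeTrajectory",
    "CrossCoalSeries",
    "SmcFormatError",
    "read_smc_final",
    "write_smc_final",
    "read_cross_coal",
    "write_cross_coal",
    "scale_to_real",
    "real_to_scaled",
    "cross_coal_to_real",
]

_FINAL_COLUMNS = ("time_index", "left_time_boundary", "right_time_boundary", "lambda")
_CROSS_COLUMNS = ("left_time_boundary", "right_time_boundary", "lambda_00", "lambda_01", "lambda_11")


class SmcFormatError(ValueError):
    """Raised when an SMC-style table violates the format contract."""


@dataclass(frozen=True)
class ScalingConstants:
    """Mutation rate per generation per site and generation time in years.

    Defaults are the values used for clownfish demographic reconstructions:
    ``mu = 4e-8`` and a generation time of 5 years.
    """

    mu: float = 4e-8
    gen_time: float = 5.0

    def __post_init__(self) -> None:
        if not (self.mu > 0 and self.gen_time > 0):
            raise ValueError("mu and gen_time must be strictly positive")


@dataclass
class ScaledRateSeries:
    """Piecewise-constant scaled coalescence rates (MSMC2 final output)."""

    time_index: np.ndarray
    left: np.ndarray
    right: np.ndarray
    lam: np.ndarray

    def __post_init__(self) -> None:
        self.time_index = np.asarray(self.time_index, dtype=int)
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        self.validate()

    def __len__(self) -> int:
        return len(self.lam)

    def validate(self) -> None:
        n = len(self.lam)
        if n == 0:
            raise SmcFormatError("empty rate series")
        if not np.array_equal(self.time_index, np.arange(n)):
            raise SmcFormatError("time_index must increase from 0 in steps of 1")
        for i in range(n):
            if not self.left[i] < self.right[i]:
                raise SmcFormatError(
                    f"row {i}: left boundary {self.left[i]} not below right {self.right[i]}"
                )
            if not self.lam[i] > 0:
                raise SmcFormatError(f"row {i}: lambda must be > 0, got {self.lam[i]}")
        if np.isinf(self.left).any():
            raise SmcFormatError("left boundaries must be finite")
        if np.isinf(self.right[:-1]).any():
            raise SmcFormatError("only the final right boundary may be infinite")
        if n > 1 and not np.allclose(self.right[:-1], self.left[1:], rtol=1e-9, atol=0.0):
            bad = int(np.flatnonzero(~np.isclose(self.right[:-1], self.left[1:]))[0])
            raise SmcFormatError(f"rows {bad}/{bad + 1}: segments not contiguous")


@dataclass
class NeTrajectory:
    """One population x replicate piecewise Ne history on real-time segments.

    Times are years before present; ``ne`` may contain NaN where an
    estimate has been masked by quality control.
    """

    species: str
    population: str
    replicate_id: str
    t_left: np.ndarray
    t_right: np.ndarray
    ne: np.ndarray

    def __post_init__(self) -> None:
        self.t_left = np.asarray(self.t_left, dtype=float)
        self.t_right = np.asarray(self.t_right, dtype=float)
        self.ne = np.asarray(self.ne, dtype=float)
        if len(self.ne) == 0:
            raise ValueError("trajectory must have at least one segment")
        if not np.all(self.t_left < self.t_right):
            raise ValueError("segments must satisfy t_left < t_right")
        if len(self.ne) > 1 and not np.allclose(self.t_right[:-1], self.t_left[1:]):
            raise ValueError("segments must be contiguous in time")
        present = ~np.isnan(self.ne)
        if not np.all(self.ne[present] > 0):
            raise ValueError("Ne must be positive where present")

    def __len__(self) -> int:
        return len(self.ne)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.species, self.population, self.replicate_id)

    def with_ne(self, ne: np.ndarray) -> "NeTrajectory":
        return replace(self, ne=np.asarray(ne, dtype=float))


@dataclass
class CrossCoalSeries:
    """Within- and cross-population coalescence rates for one pair.

    ``time_unit`` records whether boundaries are scaled (dimensionless,
    the on-disk dialect) or already converted to years before present.
    """

    left: np.ndarray
    right: np.ndarray
    lam00: np.ndarray
    lam01: np.ndarray
    lam11: np.ndarray
    time_unit: str = "scaled"

    def __post_init__(self) -> None:
        for name in ("left", "right", "lam00", "lam01", "lam11"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.time_unit not in ("scaled", "years"):
            raise ValueError("time_unit must be 'scaled' or 'years'")
        n = len(self.lam00)
        if n == 0:
            raise SmcFormatError("empty cross-coalescence series")
        for i in range(n):
            if not self.left[i] < self.right[i]:
                raise SmcFormatError(f"row {i}: non-increasing time boundaries")
            rates = (self.lam00[i], self.lam01[i], self.lam11[i])
            if any(r < 0 for r in rates):
                raise SmcFormatError(f"row {i}: negative coalescence rate")
            if all(r == 0 for r in rates):
                raise SmcFormatError(f"row {i}: all three rates are zero")
        if n > 1 and not np.allclose(self.right[:-1], self.left[1:], rtol=1e-9, atol=0.0):
            raise SmcFormatError("cross-coalescence segments not contiguous")

    def __len__(self) -> int:
        return len(self.lam00)


def _parse_float(token: str, row: int, col: str) -> float:
    token = token.strip()
    if token == "" or token.lower() in ("inf", "+inf", "infinity"):
        return math.inf
    try:
        return float(token)
    except ValueError as exc:
        raise SmcFormatError(f"row {row}: cannot parse {col}={token!r}") from exc


def _read_table(path, required: tuple[str, ...]) -> dict[str, list[float]]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise SmcFormatError(f"{path}: empty file")
    header = [c.strip() for c in lines[0].split("\t")]
    missing = [c for c in required if c not in header]
    if missing:
        raise SmcFormatError(f"{path}: missing column(s) {missing}; header was {header}")
    idx = {c: header.index(c) for c in required}
    out: dict[str, list[float]] = {c: [] for c in required}
    for row, ln in enumerate(lines[1:]):
        parts = ln.split("\t")
        if len(parts) < len(header):
            raise SmcFormatError(f"row {row}: expected {len(header)} fields, got {len(parts)}")
        for c in required:
            out[c].append(_parse_float(parts[idx[c]], row, c))
    return out


def read_smc_final(path) -> ScaledRateSeries:
    """Parse an MSMC2-style final table (tab-separated, header names columns).

    Column order is taken from the header; blank or ``inf`` right boundaries
    in the last row are read as infinity; trailing blank lines are ignored.
    """
    cols = _read_table(path, _FINAL_COLUMNS)
    return ScaledRateSeries(
        time_index=np.asarray(cols["time_index"], dtype=float).astype(int),
        left=cols["left_time_boundary"],
        right=cols["right_time_boundary"],
        lam=cols["lambda"],
    )


def _fmt(x: float) -> str:
    if math.isinf(x):
        return "inf"
    return repr(float(x))


def write_smc_final(series: ScaledRateSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_FINAL_COLUMNS) + "\n")
        for i in range(len(series)):
            fh.write(
                f"{series.time_index[i]}\t{_fmt(series.left[i])}"
                f"\t{_fmt(series.right[i])}\t{_fmt(series.lam[i])}\n"
            )


def read_cross_coal(path) -> CrossCoalSeries:
    """Parse a combined cross-coalescence table (lambda_00/01/11)."""
    cols = _read_table(path, _CROSS_COLUMNS)
    return CrossCoalSeries(
        left=cols["left_time_boundary"],
        right=cols["right_time_boundary"],
        lam00=cols["lambda_00"],
        lam01=cols["lambda_01"],
        lam11=cols["lambda_11"],
    )


def write_cross_coal(series: CrossCoalSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_CROSS_COLUMNS) + "\n")
        for i in range(len(series)):
            fh.write(
                f"{_fmt(series.left[i])}\t{_fmt(series.right[i])}\t{_fmt(series.lam00[i])}"
                f"\t{_fmt(series.lam01[i])}\t{_fmt(series.lam11[i])}\n"
            )


def scale_to_real(
    series: ScaledRateSeries,
    c: ScalingConstants,
    species: str = "",
    population: str = "",
    replicate_id: str = "main",
) -> NeTrajectory:
    """Convert scaled boundaries/rates to years before present and Ne.

    ``t_years = scaled_time / mu * gen_time`` and ``Ne = 1 / (2 mu lambda)``.
    An infinite final right boundary is preserved.
    """
    return NeTrajectory(
        species=species,
        population=population,
        replicate_id=replicate_id,
        t_left=series.left / c.mu * c.gen_time,
        t_right=series.right / c.mu * c.gen_time,
        ne=1.0 / (2.0 * c.mu * series.lam),
    )


def real_to_scaled(traj: NeTrajectory, c: ScalingConstants) -> ScaledRateSeries:
    """Inverse of :func:`scale_to_real`; requires no masked Ne values."""
    if np.isnan(traj.ne).any():
        raise ValueError("cannot rescale a trajectory with masked Ne values")
    return ScaledRateSeries(
        time_index=np.arange(len(traj)),
        left=traj.t_left * c.mu / c.gen_time,
        right=traj.t_right * c.mu / c.gen_time,
        lam=1.0 / (2.0 * c.mu * traj.ne),
    )


def cross_coal_to_real(series: CrossCoalSeries, c: ScalingConstants) -> CrossCoalSeries:
    """Convert a scaled cross-coalescence series onto the years axis."""
    if series.time_unit == "years":
        return series
    return CrossCoalSeries(
        left=series.left / c.mu * c.gen_time,
        right=series.right / c.mu * c.gen_time,
        lam00=series.lam00,
        lam01=series.lam01,
        lam11=series.lam11,
        time_unit="years",
    )
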
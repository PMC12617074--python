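"""Synthetic inputs with the statistical structure the pipeline assumes.

Real inputs to this analysis are whole-genome SMC reconstructions and
filtered VCFs from hundreds of reef-fish genomes.  This module generates
desk-scale stand-ins with *known* parameters so every downstream stage has
an oracle:

* a glacial-cycle sea-level curve (sum of ~100 ky and ~41 ky orbital
  sinusoids plus smooth noise, clamped to [-140, +10] m);
* piecewise-constant Ne trajectories on log-spaced time segments whose
  log-Ne responds linearly to the standardized sea level with a
  host-category-specific coefficient, plus AR(1) lognormal replicate
  noise — also emitted in SMC scaled units so the full pipeline runs
  end-to-end;
* cross-coalescence-rate tables with a known split time (step or
  logistic);
* genotype matrices under the Balding–Nichols island model with a known
  FST, written as VCF 4.2.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .harmonize import standardize
from .popgen import GenotypeMatrix
from .smc_io import (
    CrossCoalSeries,
    NeTrajectory,
    ScalingConstants,
    real_to_scaled,
    write_smc_final,
)

__all__ = [
    "SeaLevelSeries",
    "ScenarioConfig",
    "BNGenotypeConfig",
    "HOST_CATEGORIES",
    "gen_sealevel",
    "gen_trajectories",
    "gen_cross_coal",
    "gen_genotypes",
    "write_sealevel_csv",
    "read_sealevel_csv",
    "write_smc_tables",
]

#: Host-specialisation groups: anemone generalists and the three
#: specialist guilds (Radianthus, Entacmaea, Stichodactyla hosts).
HOST_CATEGORIES = ("generalist", "RM", "EQ", "SD")


@dataclass
class SeaLevelSeries:
    """Sea level (m relative to present) against age (years BP)."""

    age: np.ndarray
    level: np.ndarray

    def __post_init__(self) -> None:
        self.age = np.asarray(self.age, dtype=float)
        self.level = np.asarray(self.level, dtype=float)
        if len(self.age) != len(self.level) or len(self.age) < 2:
            raise ValueError("age and level must be equal length >= 2")
        if not np.all(np.diff(self.age) > 0):
            raise ValueError("ages must be strictly increasing")

    @property
    def max_age(self) -> float:
        return float(self.age[-1])

    def at(self, ages: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(ages, dtype=float), self.age, self.level)


def gen_sealevel(max_age: float = 1e6, step: float = 1000.0, seed: int = 0) -> SeaLevelSeries:
    """Glacial-cycle-like sea-level curve, deterministic per seed.

    Two cosine terms (100 ky and 41 ky periods, both zero at the present)
    pull the level down to glacial lowstands; smoothed random noise
    (re-zeroed at age 0) adds realisation-specific structure.  Levels are
    clamped to [-140, +10] m, and level(0) is 0 m by construction.
    """
    if not max_age >= step > 0:
        raise ValueError("require max_age >= step > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, max_age + step / 2, step)
    level = 40.0 * (np.cos(2 * np.pi * t / 100_000.0) - 1.0)
    level += 20.0 * (np.cos(2 * np.pi * t / 41_000.0) - 1.0)
    raw = rng.normal(0.0, 1.0, len(t))
    kernel = np.ones(21) / 21.0
    smooth = np.convolve(raw, kernel, mode="same")
    smooth = 5.0 * (smooth - smooth[0])
    level = np.clip(level + smooth, -140.0, 10.0)
    return SeaLevelSeries(age=t, level=level)


def write_sealevel_csv(sea: SeaLevelSeries, path) -> None:
    pd.DataFrame({"age_years": sea.age, "level_m": sea.level}).to_csv(path, index=False)


def read_sealevel_csv(path) -> SeaLevelSeries:
    df = pd.read_csv(path, comment="#")
    return SeaLevelSeries(age=df["age_years"].to_numpy(), level=df["level_m"].to_numpy())


@dataclass
class ScenarioConfig:
    """Study design for the trajectory generator.

    ``n_species`` gives the number of species per host category and
    ``gamma`` the per-category linear response of log-Ne to standardized
    sea level; ``noise_sd`` and ``ar_coef`` control the AR(1) lognormal
    replicate noise across segments.  50 bootstrap replicates per
    population (plus one 'main' run) matches the uncertainty design of the
    source reconstructions.
    """

    n_species: dict[str, int] = field(default_factory=lambda: {"generalist": 3, "RM": 3})
    pops_per_species: int = 2
    n_bootstraps: int = 50
    base_ne: float = 20_000.0
    gamma: dict[str, float] = field(default_factory=lambda: {"generalist": 0.0, "RM": -1.0})
    noise_sd: float = 0.2
    ar_coef: float = 0.3
    n_segments: int = 20
    contam_frac: float = 0.0
    contam_factor: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ar_coef < 1.0:
            raise ValueError("ar_coef must be in [0, 1)")
        if self.noise_sd < 0 or self.base_ne <= 0 or self.n_segments < 2:
            raise ValueError("invalid scenario configuration")
        for cat in self.n_species:
            if cat not in self.gamma:
                raise ValueError(f"no gamma coefficient for host category {cat!r}")


def _ar1(rng: np.random.Generator, n: int, sd: float, ar: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    e = np.empty(n)
    e[0] = rng.normal(0.0, 1.0)
    innov = rng.normal(0.0, 1.0, n - 1) * np.sqrt(1.0 - ar**2)
    for k in range(1, n):
        e[k] = ar * e[k - 1] + innov[k - 1]
    return sd * e


def gen_trajectories(
    cfg: ScenarioConfig, sea: SeaLevelSeries
) -> tuple[list[NeTrajectory], pd.DataFrame]:
    """Piecewise Ne trajectories responding to sea level, plus metadata.

    Segment boundaries are log-spaced over [100, max_age] years and shared
    by all replicates of a population.  For each replicate,
    ``log Ne = log(base_ne) + gamma[host] * z(sea at midpoint) + AR(1)
    noise``; the 'main' replicate receives noise like any bootstrap.  A
    ``contam_frac`` fraction of bootstrap replicates gets Ne inflated by
    ``contam_factor`` over the middle third of segments, to exercise the
    outlier filter.

    Returns the trajectory list and a per-population metadata table
    (species, population, host_category, latitude, longitude).
    """
    rng = np.random.default_rng(cfg.seed)
    bounds = np.geomspace(100.0, sea.max_age, cfg.n_segments + 1)
    t_left, t_right = bounds[:-1], bounds[1:]
    t_mid = (t_left + t_right) / 2.0
    sea_z = standardize(sea.at(t_mid))
    mid3 = slice(cfg.n_segments // 3, 2 * cfg.n_segments // 3)

    trajectories: list[NeTrajectory] = []
    meta_rows = []
    for cat, n_sp in cfg.n_species.items():
        for s in range(n_sp):
            species = f"{cat}_sp{s + 1}"
            for p in range(cfg.pops_per_species):
                pop = f"{species}_pop{p + 1}"
                meta_rows.append(
                    {
                        "species": species,
                        "population": pop,
                        "host_category": cat,
                        "latitude": float(rng.uniform(-25.0, 25.0)),
                        "longitude": float(rng.uniform(95.0, 175.0)),
                    }
                )
                signal = np.log(cfg.base_ne) + cfg.gamma[cat] * sea_z
                reps = ["main"] + [f"bs{i + 1:02d}" for i in range(cfg.n_bootstraps)]
                for rep in reps:
                    noise = (
                        _ar1(rng, cfg.n_segments, cfg.noise_sd, cfg.ar_coef)
                        if cfg.noise_sd > 0
                        else np.zeros(cfg.n_segments)
                    )
                    ne = np.exp(signal + noise)
                    if rep != "main" and rng.random() < cfg.contam_frac:
                        ne = ne.copy()
                        ne[mid3] *= cfg.contam_factor
                    trajectories.append(
                        NeTrajectory(
                            species=species,
                            population=pop,
                            replicate_id=rep,
                            t_left=t_left,
                            t_right=t_right,
                            ne=ne,
                        )
                    )
    return trajectories, pd.DataFrame(meta_rows)


def write_smc_tables(
    trajectories: list[NeTrajectory], c: ScalingConstants, outdir
) -> list[str]:
    """Emit each trajectory as an MSMC2-style scaled table in ``outdir``.

    File names encode species.population.replicate so the pipeline can
    rebuild labels on read.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for traj in trajectories:
        name = f"{traj.species}.{traj.population}.{traj.replicate_id}.final.txt"
        write_smc_final(real_to_scaled(traj, c), outdir / name)
        paths.append(name)
    return paths


def gen_cross_coal(
    T_split: float,
    N: float = 20_000.0,
    shape: str = "logistic",
    logistic_scale: float | None = None,
    c: ScalingConstants = ScalingConstants(),
    t_min: float = 100.0,
    t_max: float = 2e6,
    n_segments: int = 32,
) -> CrossCoalSeries:
    """Cross-coalescence table with a known split at ``T_split`` years.

    Within-population rates are constant at ``1/(2 mu N)`` (scaled units);
    the cross rate rises from 0 (recent, isolated) to the within rate
    (ancient, panmictic) either as a step at ``T_split`` or as a logistic
    centred there, so the relative cross-coalescence rate equals 0.5
    exactly at ``T_split`` for the logistic shape.  Time boundaries are
    log-spaced over [t_min, t_max] and emitted in scaled units.
    """
    if shape not in ("step", "logistic"):
        raise ValueError("shape must be 'step' or 'logistic'")
    if not t_min < T_split < t_max:
        raise ValueError(f"T_split {T_split} outside time span [{t_min}, {t_max}]")
    if logistic_scale is None:
        logistic_scale = T_split / 10.0
    bounds = np.geomspace(t_min, t_max, n_segments + 1)
    t_mid = (bounds[:-1] + bounds[1:]) / 2.0
    lam_within = np.full(n_segments, 1.0 / (2.0 * c.mu * N))
    if shape == "step":
        frac = (t_mid >= T_split).astype(float)
    else:
        frac = 1.0 / (1.0 + np.exp(-(t_mid - T_split) / logistic_scale))
    scale = c.mu / c.gen_time  # years -> scaled time
    return CrossCoalSeries(
        left=bounds[:-1] * scale,
        right=bounds[1:] * scale,
        lam00=lam_within,
        lam01=lam_within * frac,
        lam11=lam_within,
        time_unit="scaled",
    )


@dataclass
class BNGenotypeConfig:
    """Balding–Nichols island-model genotype harness.

    Ancestral allele frequencies are Uniform(0.05, 0.95); each population's
    frequency is Beta-distributed around the ancestral one with
    concentration set by ``fst_target`` (Wright's F); diploid genotypes are
    Binomial(2, population frequency).
    """

    n_pops: int = 2
    n_diploids: int = 25
    n_sites: int = 5000
    fst_target: float = 0.10
    chrom_length: int = 10_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fst_target < 1.0:
            raise ValueError("fst_target must be in (0, 1)")
        if self.n_sites < 1 or self.n_pops < 1 or self.n_diploids < 1:
            raise ValueError("invalid genotype configuration")
        if self.n_sites > self.chrom_length:
            raise ValueError("more sites than positions available")


def gen_genotypes(
    cfg: BNGenotypeConfig, vcf_path=None, meta_path=None
) -> GenotypeMatrix:
    """Genotypes under the Balding–Nichols model; optional VCF + metadata.

    Deterministic per seed (identical VCF bytes across runs).  Positions
    are uniform without replacement over ``chrom_length``.
    """
    rng = np.random.default_rng(cfg.seed)
    positions = np.sort(rng.choice(cfg.chrom_length, size=cfg.n_sites, replace=False)) + 1
    p_anc = rng.uniform(0.05, 0.95, cfg.n_sites)
    F = cfg.fst_target
    shape1 = p_anc * (1.0 - F) / F
    shape2 = (1.0 - p_anc) * (1.0 - F) / F
    geno = np.empty((cfg.n_sites, cfg.n_pops * cfg.n_diploids), dtype=np.int8)
    pops, samples = [], []
    for k in range(cfg.n_pops):
        pop = f"pop{k + 1}"
        p_pop = rng.beta(shape1, shape2)
        g = rng.binomial(2, p_pop[:, None], size=(cfg.n_sites, cfg.n_diploids))
        geno[:, k * cfg.n_diploids : (k + 1) * cfg.n_diploids] = g
        pops.extend([pop] * cfg.n_diploids)
        samples.extend(f"{pop}_ind{j + 1:02d}" for j in range(cfg.n_diploids))
    G = GenotypeMatrix(
        chrom="chr1",
        positions=positions,
        genotypes=geno,
        samples=samples,
        pops=np.asarray(pops, dtype=object),
    )
    if vcf_path is not None:
        _write_vcf(G, cfg.chrom_length, vcf_path)
    if meta_path is not None:
        _write_genotype_meta(G, meta_path, seed=cfg.seed)
    return G


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def _write_vcf(G: GenotypeMatrix, chrom_length: int, path) -> None:
    """Minimal deterministic VCF 4.2 writer (GT only, REF=A/ALT=T)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={G.chrom},length={chrom_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(G.samples) + "\n")
        for i in range(G.n_sites):
            gts = "\t".join(_GT_STR[int(g)] for g in G.genotypes[i])
            fh.write(f"{G.chrom}\t{G.positions[i]}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def _write_genotype_meta(G: GenotypeMatrix, path, seed: int = 0) -> None:
    """Sample metadata CSV with deterministic per-population coordinates."""
    rng = np.random.default_rng(seed + 10_000)
    pops = sorted(set(G.pops))
    coords = {
        pop: (float(rng.uniform(-25.0, 25.0)), float(rng.uniform(95.0, 175.0)))
        for pop in pops
    }
    cats = {pop: HOST_CATEGORIES[i % len(HOST_CATEGORIES)] for i, pop in enumerate(pops)}
    rows = [
        {
            "sample": s,
            "species": "simulated",
            "population": p,
            "latitude": coords[p][0],
            "longitude": coords[p][1],
            "host_category": cats[p],
        }
        for s, p in zip(G.samples, G.pops)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
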
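"""Stage orchestration: simulate -> harmonize -> qc -> split -> summarize ->
popgen -> model -> adjust.

Each stage reads only files below the run's output directory, writes its
artifacts as CSV/TSV with a header comment carrying the resolved-config
hash and seed, and is idempotent: re-running with the same config produces
byte-identical outputs.  Dependent stages check that their upstream
artifacts exist and fail naming the missing file.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import harmonize as hz
from . import qc as qcmod
from . import split_time as st
from . import stats as rs
from . import synthetic as syn
from .config import RunConfig
from .popgen import maf_filter, pairwise_summary, pop_site_pi, read_vcf, window_average
from .smc_io import read_cross_coal, read_smc_final, scale_to_real

__all__ = ["STAGES", "run_stage"]

log = logging.getLogger("demres")

STAGES = (
    "simulate",
    "harmonize",
    "qc",
    "split",
    "summarize",
    "popgen",
    "model",
    "adjust",
    "all",
)


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# demres config_hash={cfg.config_hash} seed={cfg.seed}\n")
        df.to_csv(fh, index=False)
    log.info("wrote %s (%d rows)", path, len(df))


def _require(*paths: Path) -> None:
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(
                f"missing dependency {p}; run the upstream stage first"
            )


def _read_csv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------- simulate

def stage_simulate(cfg: RunConfig, outdir: Path) -> None:
    sim = outdir / "sim"
    sim.mkdir(parents=True, exist_ok=True)
    sea = syn.gen_sealevel(cfg.sealevel_max_age, cfg.sealevel_step, cfg.seed_sealevel)
    syn.write_sealevel_csv(sea, sim / "sealevel.csv")

    trajs, popmeta = syn.gen_trajectories(cfg.scenario, sea)
    _write_csv(popmeta, sim / "populations.csv", cfg)
    syn.write_smc_tables(trajs, cfg.scaling, sim / "smc")
    log.info("simulated %d trajectories for %d populations", len(trajs), len(popmeta))

    G = syn.gen_genotypes(cfg.genotypes, vcf_path=sim / "genotypes.vcf")
    syn._write_genotype_meta(
        G, sim / "samples.csv", seed=cfg.genotypes.seed,
    )
    # regroup genotype populations into pseudo-species for pairwise models
    samples = pd.read_csv(sim / "samples.csv")
    pops = sorted(samples["population"].unique())
    k = cfg.genotype_pops_per_species
    species_of = {p: f"sp{i // k + 1}" for i, p in enumerate(pops)}
    cats = {
        f"sp{j + 1}": syn.HOST_CATEGORIES[j % len(syn.HOST_CATEGORIES)]
        for j in range((len(pops) + k - 1) // k)
    }
    samples["species"] = samples["population"].map(species_of)
    samples["host_category"] = samples["species"].map(cats)
    samples.to_csv(sim / "samples.csv", index=False)

    # cross-coalescence tables with known split times for within-species pairs
    rng = np.random.default_rng(cfg.seed_splits)
    cc_dir = sim / "crosscoal"
    cc_dir.mkdir(exist_ok=True)
    truth = []
    for sp in sorted(set(species_of.values())):
        members = [p for p in pops if species_of[p] == sp]
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                t_split = float(10 ** rng.uniform(np.log10(5e4), np.log10(5e5)))
                series = syn.gen_cross_coal(
                    t_split, N=cfg.scenario.base_ne, shape="logistic", c=cfg.scaling
                )
                from .smc_io import write_cross_coal

                write_cross_coal(series, cc_dir / f"{a}__{b}.combined.txt")
                truth.append(
                    {"species": sp, "pop1": a, "pop2": b, "true_split_years": t_split}
                )
    _write_csv(pd.DataFrame(truth), sim / "true_split_times.csv", cfg)


# -------------------------------------------------------------- harmonize

def _load_ensemble(cfg: RunConfig, outdir: Path) -> tuple[hz.TrajectoryEnsemble, syn.SeaLevelSeries, np.ndarray]:
    sim = outdir / "sim"
    _require(sim / "sealevel.csv", sim / "populations.csv", sim / "smc")
    sea = syn.read_sealevel_csv(sim / "sealevel.csv")
    popmeta = _read_csv(sim / "populations.csv")
    host_of_species = dict(zip(popmeta["species"], popmeta["host_category"]))
    trajs = []
    for path in sorted((sim / "smc").glob("*.final.txt")):
        species, population, replicate = path.name.split(".")[:3]
        trajs.append(
            scale_to_real(read_smc_final(path), cfg.scaling, species, population, replicate)
        )
    ens = hz.build_ensemble(trajs, host_of_species)
    aligned = hz.align_covariate(sea.age, sea.level, ens.grid)
    return ens, sea, aligned


def stage_harmonize(cfg: RunConfig, outdir: Path) -> None:
    ens, _, aligned = _load_ensemble(cfg, outdir)
    _write_csv(ens.to_long(aligned), outdir / "harmonized" / "ensemble_long.csv", cfg)


# --------------------------------------------------------------------- qc

def _qc_filtered(cfg: RunConfig, outdir: Path) -> tuple[hz.TrajectoryEnsemble, np.ndarray, qcmod.QCReport, qcmod.QCReport]:
    ens, _, aligned = _load_ensemble(cfg, outdir)
    if cfg.exclusions:
        ens = qcmod.apply_exclusions(ens, [tuple(x) for x in cfg.exclusions])
    epoch = cfg.epoch_by_name(cfg.qc_outlier_epoch)
    ens, rep_report = qcmod.flag_outlier_replicates(
        ens, epoch, q=cfg.qc_outlier_q, pool=cfg.qc_pool
    )
    ens, trim_report = qcmod.apply_trim(ens, q=cfg.qc_trim_q, mode=cfg.qc_trim_mode)
    return ens, aligned, rep_report, trim_report


def stage_qc(cfg: RunConfig, outdir: Path) -> None:
    _require(outdir / "harmonized" / "ensemble_long.csv")
    ens, aligned, rep_report, trim_report = _qc_filtered(cfg, outdir)
    qc_dir = outdir / "qc"
    _write_csv(rep_report.removed_replicates, qc_dir / "removed_replicates.csv", cfg)
    _write_csv(trim_report.masked_points, qc_dir / "masked_points.csv", cfg)
    _write_csv(ens.to_long(aligned), qc_dir / "ensemble_qc_long.csv", cfg)
    log.info(
        "qc: removed %d replicates, masked %d values",
        len(rep_report.removed_replicates),
        len(trim_report.masked_points),
    )


# ------------------------------------------------------------------ split

def stage_split(cfg: RunConfig, outdir: Path) -> None:
    sim = outdir / "sim"
    _require(sim / "crosscoal", sim / "true_split_times.csv")
    truth = _read_csv(sim / "true_split_times.csv")
    rows = []
    for _, rec in truth.iterrows():
        path = sim / "crosscoal" / f"{rec.pop1}__{rec.pop2}.combined.txt"
        _require(path)
        curve = st.rccr(read_cross_coal(path), cfg.scaling)
        est = st.estimate_split(
            curve,
            threshold=cfg.split_threshold,
            crossing=cfg.split_crossing,
            smooth=cfg.split_smooth,
        )
        rows.append(
            {
                "species": rec.species,
                "pop1": rec.pop1,
                "pop2": rec.pop2,
                "split_years": est.years,
                "flag": est.flag,
            }
        )
    _write_csv(pd.DataFrame(rows), outdir / "split" / "split_times.csv", cfg)


# -------------------------------------------------------------- summarize

def stage_summarize(cfg: RunConfig, outdir: Path) -> None:
    _require(outdir / "qc" / "ensemble_qc_long.csv")
    ens, _, _, _ = _qc_filtered(cfg, outdir)
    hm = hz.harmonic_mean_table(ens, cfg.epochs)
    _write_csv(hm, outdir / "summarize" / "harmonic_means.csv", cfg)


# ----------------------------------------------------------------- popgen

def stage_popgen(cfg: RunConfig, outdir: Path) -> None:
    sim = outdir / "sim"
    _require(sim / "genotypes.vcf", sim / "samples.csv")
    samples = _read_csv(sim / "samples.csv")
    pop_of = dict(zip(samples["sample"], samples["population"]))
    G = read_vcf(sim / "genotypes.vcf", pop_of)
    G = maf_filter(G, cfg.maf)
    log.info("popgen: %d sites after MAF filter", G.n_sites)

    pi_frames = []
    for pop in sorted(set(G.pops)):
        pi = pop_site_pi(G, pop)
        w = window_average(
            G.positions - 1, pi, cfg.pi_window, chrom=G.chrom,
            chrom_length=cfg.genotypes.chrom_length,
        )
        w.insert(0, "population", pop)
        pi_frames.append(w)
    _write_csv(pd.concat(pi_frames, ignore_index=True), outdir / "popgen" / "pi_windows.csv", cfg)

    coords = samples.drop_duplicates("population")[["population", "latitude", "longitude"]]
    pw = pairwise_summary(
        G, coords, maf=cfg.maf, dxy_window=cfg.dxy_window,
        chrom_length=cfg.genotypes.chrom_length,
    )
    _write_csv(pw, outdir / "popgen" / "pairwise.csv", cfg)


# ------------------------------------------------------------------ model

def stage_model(cfg: RunConfig, outdir: Path) -> None:
    _require(
        outdir / "qc" / "ensemble_qc_long.csv",
        outdir / "summarize" / "harmonic_means.csv",
    )
    ens, aligned, _, _ = _qc_filtered(cfg, outdir)
    table = rs.build_model_table(ens, aligned)
    fit = rs.fit_ne_glmm(
        table,
        backend=cfg.glmm_backend,
        pop_fixed=cfg.pop_fixed,
        replicate_sea_slope=cfg.replicate_sea_slope,
    )
    coef = fit.coefficients.reset_index(names="term")
    coef["backend"] = fit.backend
    coef["converged"] = fit.converged
    coef["n_rows"] = fit.n_rows
    _write_csv(coef, outdir / "model" / "glmm_coefficients.csv", cfg)

    fan = rs.functional_anova(ens, B=cfg.fanova_B, seed=cfg.seed_fanova)
    _write_csv(
        pd.DataFrame(
            [
                {
                    "global_f": fan.global_f,
                    "p_value": fan.p_value,
                    "n_perm": fan.n_perm,
                    "seed": fan.seed,
                }
            ]
        ),
        outdir / "model" / "fanova.csv",
        cfg,
    )

    hm = _read_csv(outdir / "summarize" / "harmonic_means.csv")
    tests = rs.epoch_rank_tests(hm, between_epoch_alternative=cfg.epoch_alternative)
    _write_csv(tests, outdir / "model" / "epoch_tests.csv", cfg)


# ----------------------------------------------------------------- adjust

def stage_adjust(cfg: RunConfig, outdir: Path) -> None:
    sim = outdir / "sim"
    _require(
        outdir / "popgen" / "pairwise.csv",
        outdir / "split" / "split_times.csv",
        sim / "samples.csv",
    )
    pw = _read_csv(outdir / "popgen" / "pairwise.csv")
    splits = _read_csv(outdir / "split" / "split_times.csv")
    samples = _read_csv(sim / "samples.csv")
    info = samples.drop_duplicates("population").set_index("population")

    merged = pw.merge(splits, on=["pop1", "pop2"], how="inner")
    merged["host_category"] = [info.at[p, "host_category"] for p in merged["pop1"]]
    merged = merged.rename(columns={"split_years": "split_time_years"})

    for statistic in ("fst", "dxy"):
        table = merged.rename(columns={statistic: "value"})[
            ["pop1", "pop2", "species", "value", "distance_km", "split_time_years", "host_category"]
        ]
        adjusted, fit = rs.adjust_pairwise(table, backend=cfg.adjust_backend)
        adjusted = adjusted.rename(columns={"value": statistic, "adjusted": f"adjusted_{statistic}"})
        _write_csv(adjusted, outdir / "adjust" / f"adjusted_{statistic}.csv", cfg)
        coef = fit.coefficients.reset_index(names="term")
        coef["backend"] = fit.backend
        coef["converged"] = fit.converged
        _write_csv(coef, outdir / "adjust" / f"fit_{statistic}.csv", cfg)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "harmonize": stage_harmonize,
    "qc": stage_qc,
    "split": stage_split,
    "summarize": stage_summarize,
    "popgen": stage_popgen,
    "model": stage_model,
    "adjust": stage_adjust,
}


def run_stage(stage: str, cfg: RunConfig, outdir) -> None:
    """Run one pipeline stage (or 'all') into ``outdir``."""
    outdir = Path(outdir)
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "resolved_config.yaml").write_text(cfg.dump_yaml())
    order = list(_STAGE_FUNCS) if stage == "all" else [stage]
    for name in order:
        log.info("=== stage %s ===", name)
        _STAGE_FUNCS[name](cfg, outdir)
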
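"""Run configuration: one structured YAML file drives the whole pipeline.

Defaults encode the analysis constants (mu = 4e-8, generation time 5 y,
QC quantiles 0.975/0.95, MAF 0.02, 10 kb pi / 50 kb dxy windows, RCCR
threshold 0.5) and a desk-scale demo scenario.  Every stochastic step takes
its seed from the single run seed via fixed offsets, and each output CSV
carries the resolved-config hash so runs are traceable and byte-identical
when repeated.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace

import yaml

from .harmonize import DEFAULT_EPOCHS, Epoch
from .smc_io import ScalingConstants
from .synthetic import BNGenotypeConfig, ScenarioConfig

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    seed: int = 1
    # scaling
    mu: float = 4e-8
    gen_time: float = 5.0
    # synthetic sea level
    sealevel_max_age: float = 1e6
    sealevel_step: float = 1000.0
    # trajectory scenario (demo scale: 2 host groups x 3 species x 2 pops,
    # 10 bootstraps)
    scenario: ScenarioConfig = field(
        default_factory=lambda: ScenarioConfig(
            n_species={"generalist": 3, "RM": 3},
            pops_per_species=2,
            n_bootstraps=10,
            gamma={"generalist": 0.0, "RM": -1.0},
        )
    )
    # epochs
    epochs: tuple[Epoch, ...] = DEFAULT_EPOCHS
    # QC
    qc_outlier_q: float = 0.975
    qc_trim_q: float = 0.95
    qc_pool: str = "species"
    qc_trim_mode: str = "literal"
    qc_outlier_epoch: str = "fluctuation_120_15ka"
    exclusions: list = field(default_factory=list)
    # split-time estimation
    split_threshold: float = 0.5
    split_crossing: str = "recent"
    split_smooth: bool = False
    # genotype harness (demo: 12 pops grouped 4-per-species, 2000 SNPs)
    genotypes: BNGenotypeConfig = field(
        default_factory=lambda: BNGenotypeConfig(
            n_pops=12, n_diploids=8, n_sites=2000, fst_target=0.10
        )
    )
    genotype_pops_per_species: int = 4
    # windowed statistics
    maf: float = 0.02
    pi_window: int = 10_000
    dxy_window: int = 50_000
    # models
    glmm_backend: str = "lmm-log"
    pop_fixed: bool = False
    replicate_sea_slope: bool = True
    fanova_B: int = 199
    epoch_alternative: str = "two-sided"
    adjust_backend: str = "lmm"

    @property
    def scaling(self) -> ScalingConstants:
        return ScalingConstants(mu=self.mu, gen_time=self.gen_time)

    # fixed offsets give every stochastic step its own stream
    @property
    def seed_sealevel(self) -> int:
        return self.seed + 1

    @property
    def seed_genotypes(self) -> int:
        return self.seed + 2

    @property
    def seed_splits(self) -> int:
        return self.seed + 3

    @property
    def seed_fanova(self) -> int:
        return self.seed + 4

    def resolved(self) -> "RunConfig":
        """Propagate the run seed into sub-configs."""
        return replace(
            self,
            scenario=replace(self.scenario, seed=self.seed),
            genotypes=replace(self.genotypes, seed=self.seed_genotypes),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["epochs"] = [
            {"name": e.name, "t_start": e.t_start, "t_end": e.t_end} for e in self.epochs
        ]
        return d

    def dump_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.dump_yaml().encode()).hexdigest()[:12]

    def epoch_by_name(self, name: str) -> Epoch:
        for e in self.epochs:
            if e.name == name:
                return e
        raise KeyError(f"no epoch named {name!r}")


def _from_dict(d: dict) -> RunConfig:
    kwargs = dict(d)
    if "scenario" in kwargs and isinstance(kwargs["scenario"], dict):
        kwargs["scenario"] = ScenarioConfig(**kwargs["scenario"])
    if "genotypes" in kwargs and isinstance(kwargs["genotypes"], dict):
        kwargs["genotypes"] = BNGenotypeConfig(**kwargs["genotypes"])
    if "epochs" in kwargs:
        kwargs["epochs"] = tuple(
            Epoch(e["name"], float(e["t_start"]), float(e["t_end"]))
            for e in kwargs["epochs"]
        )
    if "exclusions" in kwargs:
        kwargs["exclusions"] = [tuple(x) for x in kwargs["exclusions"]]
    return RunConfig(**kwargs)


def load_config(path=None, **overrides) -> RunConfig:
    """Load YAML config (defaults where absent) and apply CLI overrides."""
    if path is None:
        cfg = RunConfig()
    else:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = _from_dict(data)
    if overrides:
        cfg = replace(cfg, **{k: v for k, v in overrides.items() if v is not None})
    return cfg.resolved()
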
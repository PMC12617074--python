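import numpy as np
import pytest

from demres.harmonize import align_covariate, build_ensemble
from demres.smc_io import NeTrajectory, ScalingConstants
from demres.synthetic import ScenarioConfig, gen_sealevel, gen_trajectories


@pytest.fixture(scope="session")
def constants():
    return ScalingConstants(mu=4e-8, gen_time=5.0)


@pytest.fixture(scope="session")
def sea():
    return gen_sealevel(max_age=1e6, step=1000.0, seed=7)


@pytest.fixture
def simple_trajectory():
    """Two contiguous segments: (0-100, Ne 100) and (100-400, Ne 300)."""
    return NeTrajectory(
        species="sp",
        population="pop",
        replicate_id="main",
        t_left=np.array([0.0, 100.0]),
        t_right=np.array([100.0, 400.0]),
        ne=np.array([100.0, 300.0]),
    )


@pytest.fixture(scope="session")
def make_ensemble(sea):
    """Factory: scenario ensemble (+ aligned sea level) from a few knobs."""

    def _make(
        gammas,
        n_species=3,
        pops_per_species=1,
        n_bootstraps=10,
        noise_sd=0.2,
        ar_coef=0.3,
        seed=0,
        base_ne=20_000.0,
    ):
        cfg = ScenarioConfig(
            n_species={cat: n_species for cat in gammas},
            pops_per_species=pops_per_species,
            n_bootstraps=n_bootstraps,
            gamma=dict(gammas),
            noise_sd=noise_sd,
            ar_coef=ar_coef,
            base_ne=base_ne,
            seed=seed,
        )
        trajs, meta = gen_trajectories(cfg, sea)
        host = dict(zip(meta["species"], meta["host_category"]))
        ens = build_ensemble(trajs, host)
        aligned = align_covariate(sea.age, sea.level, ens.grid)
        return ens, aligned

    return _make
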
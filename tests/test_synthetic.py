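import numpy as np
import pytest

from demres.harmonize import standardize
from demres.popgen import wc_fst
from demres.smc_io import ScalingConstants
from demres.synthetic import (
    BNGenotypeConfig,
    ScenarioConfig,
    gen_cross_coal,
    gen_genotypes,
    gen_sealevel,
    gen_trajectories,
)


class TestSeaLevel:
    def test_deterministic_per_seed(self):
        s1 = gen_sealevel(1e6, 1000, seed=3)
        s2 = gen_sealevel(1e6, 1000, seed=3)
        np.testing.assert_array_equal(s1.level, s2.level)

    def test_row_count(self):
        s = gen_sealevel(1e6, 1000, seed=0)
        assert len(s.age) == 1001

    def test_bounds_over_seed_sweep(self):
        for seed in range(20):
            s = gen_sealevel(5e5, 2000, seed=seed)
            assert s.level.min() >= -140.0
            assert s.level.max() <= 10.0
            assert -5.0 <= s.level[0] <= 5.0


class TestTrajectories:
    def test_null_response_is_flat(self, sea):
        cfg = ScenarioConfig(
            n_species={"generalist": 1},
            pops_per_species=1,
            n_bootstraps=2,
            gamma={"generalist": 0.0},
            noise_sd=0.0,
            base_ne=5000.0,
            seed=1,
        )
        trajs, _ = gen_trajectories(cfg, sea)
        for t in trajs:
            np.testing.assert_allclose(t.ne, 5000.0)

    def test_sea_response_correlates(self, sea):
        cfg = ScenarioConfig(
            n_species={"RM": 1},
            pops_per_species=1,
            n_bootstraps=0,
            gamma={"RM": 0.5},
            noise_sd=0.0,
            seed=2,
        )
        trajs, _ = gen_trajectories(cfg, sea)
        t = trajs[0]
        z = standardize(sea.at((t.t_left + t.t_right) / 2))
        r = np.corrcoef(z, np.log(t.ne))[0, 1]
        assert r > 0.9

    def test_replicate_count(self, sea):
        cfg = ScenarioConfig(
            n_species={"generalist": 1},
            pops_per_species=1,
            n_bootstraps=50,
            gamma={"generalist": 0.0},
            seed=3,
        )
        trajs, _ = gen_trajectories(cfg, sea)
        reps = {t.replicate_id for t in trajs}
        assert len(trajs) == 51 and "main" in reps

    def test_metadata_one_row_per_population(self, sea):
        cfg = ScenarioConfig(
            n_species={"generalist": 2, "RM": 1},
            pops_per_species=3,
            n_bootstraps=1,
            gamma={"generalist": 0.0, "RM": -1.0},
            seed=4,
        )
        _, meta = gen_trajectories(cfg, sea)
        assert len(meta) == 9
        assert set(meta["host_category"]) == {"generalist", "RM"}

    def test_pure_function_of_seed(self, sea):
        cfg = ScenarioConfig(seed=11)
        t1, m1 = gen_trajectories(cfg, sea)
        t2, m2 = gen_trajectories(cfg, sea)
        assert m1.equals(m2)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.ne, b.ne)

    def test_contamination_inflates_some_bootstraps(self, sea):
        cfg = ScenarioConfig(
            n_species={"generalist": 1},
            pops_per_species=1,
            n_bootstraps=20,
            gamma={"generalist": 0.0},
            noise_sd=0.0,
            contam_frac=0.3,
            seed=5,
        )
        trajs, _ = gen_trajectories(cfg, sea)
        inflated = [t for t in trajs if t.ne.max() > 2 * cfg.base_ne]
        assert 0 < len(inflated) < len(trajs)
        assert all(t.replicate_id != "main" for t in inflated)


class TestCrossCoal:
    def test_within_rates_from_ne(self, constants):
        s = gen_cross_coal(1e5, N=1000, c=constants)
        np.testing.assert_allclose(s.lam00, 12_500.0)
        np.testing.assert_allclose(s.lam11, 12_500.0)

    def test_step_shape_rccr_binary(self, constants):
        from demres.split_time import rccr

        s = gen_cross_coal(1e5, N=1000, shape="step", c=constants)
        curve = rccr(s, constants)
        before = curve.r[curve.t_mid < 1e5]
        after = curve.r[curve.t_mid >= 1e5]
        assert np.all(before == 0.0) and np.all(after == 1.0)

    def test_logistic_midpoint_is_half(self, constants):
        t_split = 123_456.0
        s = gen_cross_coal(t_split, N=1000, shape="logistic", c=constants)
        # evaluate RCCR analytically at the split itself
        from demres.split_time import estimate_split, rccr

        est = estimate_split(rccr(s, constants))
        assert est.flag == "ok"
        assert est.years == pytest.approx(t_split, rel=0.1)


class TestGenotypes:
    def test_low_f_limit_frequencies_agree(self):
        # as F -> 0 the Beta concentrates on the ancestral frequency; with
        # many chromosomes the sample frequencies of the two demes agree
        cfg = BNGenotypeConfig(
            n_pops=2, n_diploids=3000, n_sites=500, fst_target=1e-6, seed=0
        )
        G = gen_genotypes(cfg)
        a1, n1 = G.allele_counts(G.pop_columns("pop1"))
        a2, n2 = G.allele_counts(G.pop_columns("pop2"))
        diff = np.abs(a1 / n1 - a2 / n2)
        assert diff.mean() < 0.01

    def test_vcf_bytes_deterministic(self, tmp_path):
        cfg = BNGenotypeConfig(n_pops=2, n_diploids=5, n_sites=50, seed=9)
        gen_genotypes(cfg, vcf_path=tmp_path / "a.vcf")
        gen_genotypes(cfg, vcf_path=tmp_path / "b.vcf")
        assert (tmp_path / "a.vcf").read_bytes() == (tmp_path / "b.vcf").read_bytes()

    def test_vcf_sample_columns(self, tmp_path):
        cfg = BNGenotypeConfig(n_pops=2, n_diploids=25, n_sites=20, seed=1)
        gen_genotypes(cfg, vcf_path=tmp_path / "g.vcf")
        header = [
            ln for ln in (tmp_path / "g.vcf").read_text().splitlines()
            if ln.startswith("#CHROM")
        ][0]
        assert len(header.split("\t")) == 9 + 50

    def test_vcf_read_back_matches_matrix(self, tmp_path):
        from demres.popgen import read_vcf

        cfg = BNGenotypeConfig(n_pops=2, n_diploids=6, n_sites=100, seed=2)
        G = gen_genotypes(cfg, vcf_path=tmp_path / "g.vcf")
        back = read_vcf(tmp_path / "g.vcf", dict(zip(G.samples, G.pops)))
        np.testing.assert_array_equal(back.positions, G.positions)
        np.testing.assert_array_equal(back.genotypes, G.genotypes)

    def test_realized_fst_tracks_target(self):
        cfg = BNGenotypeConfig(
            n_pops=2, n_diploids=25, n_sites=4000, fst_target=0.25, seed=3
        )
        G = gen_genotypes(cfg)
        _, theta = wc_fst(G, "pop1", "pop2")
        assert theta == pytest.approx(0.25, abs=0.04)
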
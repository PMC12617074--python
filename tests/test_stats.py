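import numpy as np
import pandas as pd
import pytest

from demres.harmonize import DEFAULT_EPOCHS, harmonic_mean_table
from demres.stats import (
    adjust_pairwise,
    build_model_table,
    epoch_rank_tests,
    fit_ne_glmm,
    functional_anova,
    rank_sum_test,
)


class TestModelTable:
    def test_row_count_and_standardization(self, make_ensemble):
        ens, aligned = make_ensemble({"generalist": 0.0, "RM": 0.0}, n_species=1,
                                     n_bootstraps=2, seed=0)
        table = build_model_table(ens, aligned)
        covered = np.sum(~np.isnan(ens.values[0]) & ~np.isnan(aligned))
        assert len(table) == covered * len(ens)
        assert abs(table["sea_z"].mean()) < 1e-9
        assert table["sea_z"].std(ddof=1) == pytest.approx(1.0)
        assert not table["Ne"].isna().any()

    def test_missing_grid_points_excluded(self, make_ensemble):
        ens, aligned = make_ensemble({"generalist": 0.0, "RM": 0.0}, n_species=1,
                                     n_bootstraps=2, seed=1)
        n_missing = int(np.isnan(ens.values).sum())
        assert n_missing > 0  # trajectories do not span the full grid
        table = build_model_table(ens, aligned)
        assert len(table) + n_missing >= ens.values.size


class TestGlmm:
    def test_planted_interaction_sign(self, make_ensemble):
        ens, aligned = make_ensemble({"generalist": 0.0, "RM": 0.5}, seed=100)
        fit = fit_ne_glmm(build_model_table(ens, aligned))
        assert fit.converged and fit.backend == "lmm-log"
        row = fit.find("sea_z", "host_category", exclude=("time_z",))
        # treatment coding: generalist vs RM baseline -> difference -0.5
        assert row.estimate < 0 and row.pvalue < 0.05

    def test_backends_agree_on_sign(self, make_ensemble):
        ens, aligned = make_ensemble({"generalist": 0.0, "RM": 0.5}, seed=101)
        table = build_model_table(ens, aligned)
        lmm = fit_ne_glmm(table, backend="lmm-log")
        glm = fit_ne_glmm(table, backend="glm-gamma")
        r1 = lmm.find("sea_z", "host_category", exclude=("time_z",))
        r2 = glm.find("sea_z", "host_category", exclude=("time_z",))
        assert np.sign(r1.estimate) == np.sign(r2.estimate)

    def test_degenerate_constant_response_flagged(self, make_ensemble):
        ens, aligned = make_ensemble({"generalist": 0.0, "RM": 0.0}, n_species=1,
                                     n_bootstraps=2, noise_sd=0.0, seed=2)
        fit = fit_ne_glmm(build_model_table(ens, aligned))
        assert not fit.converged
        assert "zero variance" in fit.notes

    def test_single_host_category_rejected(self, make_ensemble):
        ens, aligned = make_ensemble({"generalist": 0.0}, n_species=2,
                                     n_bootstraps=2, seed=3)
        with pytest.raises(ValueError, match="host"):
            fit_ne_glmm(build_model_table(ens, aligned))


class TestFanova:
    def test_reproducible_per_seed(self, make_ensemble):
        ens, _ = make_ensemble({"generalist": -0.5, "RM": -0.5}, n_bootstraps=1, seed=4)
        f1 = functional_anova(ens, B=99, seed=5)
        f2 = functional_anova(ens, B=99, seed=5)
        assert f1.p_value == f2.p_value and f1.global_f == f2.global_f

    def test_separated_groups_significant(self, make_ensemble, sea):
        from demres.harmonize import align_covariate, build_ensemble
        from demres.synthetic import ScenarioConfig, gen_trajectories

        trajs, metas = [], []
        for cat, base, seed in (("generalist", 20_000.0, 11), ("RM", 60_000.0, 12)):
            cfg = ScenarioConfig(
                n_species={cat: 4}, pops_per_species=1, n_bootstraps=1,
                gamma={cat: 0.0}, noise_sd=0.1, base_ne=base, seed=seed,
            )
            t, m = gen_trajectories(cfg, sea)
            trajs += t
            metas.append(m)
        meta = pd.concat(metas)
        host = dict(zip(meta["species"], meta["host_category"]))
        ens = build_ensemble(trajs, host)
        f = functional_anova(ens, B=199, seed=6)
        assert f.p_value <= 0.05

    def test_single_group_errors(self, make_ensemble):
        ens, _ = make_ensemble({"generalist": 0.0}, n_bootstraps=1, seed=7)
        with pytest.raises(ValueError, match="2 groups"):
            functional_anova(ens, B=9, seed=0)

    def test_single_trajectory_group_errors(self, make_ensemble, sea):
        from demres.harmonize import build_ensemble
        from demres.synthetic import ScenarioConfig, gen_trajectories

        cfg = ScenarioConfig(
            n_species={"generalist": 1, "RM": 1}, pops_per_species=1,
            n_bootstraps=0, gamma={"generalist": 0.0, "RM": 0.0}, seed=8,
        )
        trajs, meta = gen_trajectories(cfg, sea)
        host = dict(zip(meta["species"], meta["host_category"]))
        ens = build_ensemble(trajs, host)
        with pytest.raises(ValueError, match=">= 2 trajectories"):
            functional_anova(ens, B=9, seed=0)


class TestEpochRankTests:
    def test_exact_rank_sum_example(self):
        # one-sided exact p over all C(6,3) = 20 arrangements
        _, p = rank_sum_test([1, 2, 3], [10, 20, 30], alternative="less")
        assert p == pytest.approx(0.05)

    def test_identical_groups_kw_zero(self):
        hm = pd.DataFrame(
            {
                "host_category": ["a"] * 3 + ["b"] * 3,
                "epoch": ["e1"] * 6,
                "harmonic_mean_ne": [100.0] * 6,
            }
        )
        out = epoch_rank_tests(hm)
        kw = out[out["test"] == "kruskal_wallis"].iloc[0]
        assert kw["statistic"] == 0.0 and kw["pvalue"] == 1.0

    def test_insufficient_data_flagged_not_dropped(self):
        hm = pd.DataFrame(
            {
                "host_category": ["a", "b"],
                "epoch": ["e1", "e1"],
                "harmonic_mean_ne": [10.0, 20.0],
            }
        )
        out = epoch_rank_tests(hm)
        assert (out["flag"] == "insufficient").any()

    def test_epoch_contrast_detects_planted_decline(self, make_ensemble):
        ens, _ = make_ensemble(
            {"generalist": 0.0, "RM": -1.0}, pops_per_species=2, seed=900
        )
        hm = harmonic_mean_table(ens, DEFAULT_EPOCHS)
        tests = epoch_rank_tests(hm, between_epoch_alternative="greater")
        rs = tests[
            (tests["test"] == "rank_sum")
            & (tests["epoch"] == "fluctuation_120_15ka")
            & (tests["epoch2"] == "rise_15_0ka")
        ].set_index("group")
        assert rs.loc["RM", "pvalue"] < 0.05
        assert rs.loc["generalist", "pvalue"] >= 0.05


def _pair_table(seed, planted_slope=0.05, noise=0.01, n_pops=12):
    rng = np.random.default_rng(seed)
    pops = [f"p{i}" for i in range(n_pops)]
    species = {p: f"sp{i // 4}" for i, p in enumerate(pops)}
    rows = []
    for i in range(n_pops):
        for j in range(i + 1, n_pops):
            rows.append(
                {
                    "pop1": pops[i],
                    "pop2": pops[j],
                    "species": species[pops[i]],
                    "distance_km": rng.uniform(100, 5000),
                    "split_time_years": rng.uniform(5e4, 5e5),
                    "host_category": ["generalist", "RM"][i % 2],
                }
            )
    df = pd.DataFrame(rows)
    dz = (df["distance_km"] - df["distance_km"].mean()) / df["distance_km"].std(ddof=1)
    df["value"] = 0.1 + planted_slope * dz + rng.normal(0, noise, len(df))
    return df, dz


class TestAdjustPairwise:
    def test_zero_coefficients_leave_values_unchanged(self):
        df, _ = _pair_table(0)
        df["value"] = 0.123  # constant response -> fitted slopes exactly 0
        adj, fit = adjust_pairwise(df)
        np.testing.assert_allclose(adj["adjusted"], df["value"], atol=1e-10)

    def test_planted_distance_slope_removed(self):
        df, dz = _pair_table(1)
        adj, fit = adjust_pairwise(df)
        slope = np.polyfit(dz, adj["adjusted"], 1)[0]
        assert abs(slope) < 0.01
        assert fit.coefficients.loc["distance_z", "estimate"] == pytest.approx(
            0.05, abs=0.01
        )

    def test_row_order_invariance(self):
        df, _ = _pair_table(2)
        adj1, _ = adjust_pairwise(df)
        shuffled = df.sample(frac=1.0, random_state=0)
        adj2, _ = adjust_pairwise(shuffled)
        merged = adj1.merge(adj2, on=["pop1", "pop2"], suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["adjusted_a"], merged["adjusted_b"])

    def test_collinear_design_names_columns(self):
        df, _ = _pair_table(3)
        df["split_time_years"] = df["distance_km"] * 2.0  # perfectly collinear
        with pytest.raises(ValueError, match="collinear"):
            adjust_pairwise(df)

    def test_too_few_pairs_rejected(self):
        df, _ = _pair_table(4)
        with pytest.raises(ValueError, match="10 pairs"):
            adjust_pairwise(df.head(5))

    def test_host_effect_ordering_preserved(self):
        df, _ = _pair_table(5)
        df.loc[df["host_category"] == "RM", "value"] += 0.05
        adj, fit = adjust_pairwise(df)
        means = adj.groupby("host_category")["adjusted"].mean()
        assert means["RM"] > means["generalist"]
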
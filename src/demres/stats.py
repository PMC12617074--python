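"""Comparative models relating Ne trajectories and pairwise statistics to
ecology.

Four analyses ask whether host-specialist populations responded to
Pleistocene sea-level change differently from generalists:

* a mixed model of Ne on standardized sea level x host category x
  standardized time with nested random effects
  (species / population / bootstrap replicate);
* a permutation functional ANOVA comparing whole Ne trajectories between
  host groups (pointwise one-way F, global statistic = mean pointwise F,
  labels permuted at the species level);
* Kruskal-Wallis tests across host groups and rank-sum tests between
  climatic epochs on weighted harmonic-mean Ne;
* a fixed-effect-removal adjustment of pairwise FST/dxy: fit the statistic
  on geographic distance + split time + host category with crossed random
  intercepts for the two populations and species, then subtract the
  distance and split-time contributions.

The response model for Ne is a Gamma GLMM with a log link in spirit; the
default fitting backend is a linear mixed model on log(Ne) (the log-link
correspondence), with a fixed-effects Gamma GLM available as a
cross-check.  Every fit reports which backend produced it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .harmonize import TrajectoryEnsemble, standardize

__all__ = [
    "FitResult",
    "FanovaResult",
    "build_model_table",
    "fit_ne_glmm",
    "functional_anova",
    "epoch_rank_tests",
    "rank_sum_test",
    "adjust_pairwise",
]


@dataclass
class FitResult:
    """Coefficient table plus fit metadata from one model backend."""

    coefficients: pd.DataFrame  # index = name; columns estimate, se, pvalue
    backend: str
    converged: bool
    n_rows: int
    notes: str = ""

    def find(self, *substrings: str, exclude: tuple[str, ...] = ()) -> pd.Series:
        """Return the unique coefficient row whose name contains all parts
        (and none of ``exclude``)."""
        names = [
            n
            for n in self.coefficients.index
            if all(s in n for s in substrings) and not any(s in n for s in exclude)
        ]
        if len(names) != 1:
            raise KeyError(f"{substrings} matches {names}")
        return self.coefficients.loc[names[0]]


def build_model_table(
    ensemble: TrajectoryEnsemble, sea_level: np.ndarray
) -> pd.DataFrame:
    """Long table of (Ne, sea_z, time_z, labels) ready for model fitting.

    One row per (species, population, replicate, grid point) where both Ne
    and the aligned sea level are non-missing; covariates are standardized
    over exactly the included rows (i.e., after all filtering).
    """
    sea_level = np.asarray(sea_level, dtype=float)
    if len(sea_level) != len(ensemble.grid):
        raise ValueError("sea_level must be aligned on the ensemble grid")
    df = ensemble.to_long(sea_level)
    df = df.dropna(subset=["Ne", "sea_level"]).reset_index(drop=True)
    if df.empty:
        raise ValueError("no rows with non-missing Ne and sea level")
    df["sea_z"] = standardize(df["sea_level"].to_numpy())
    df["time_z"] = standardize(df["time"].to_numpy())
    df["log_ne"] = np.log(df["Ne"].to_numpy())
    return df


def _fit_mixedlm(model, methods: tuple[str, ...] = ("lbfgs", "powell")):
    """Fit a MixedLM trying optimizers in turn; variance components at the
    boundary often defeat gradient methods, where Powell still converges."""
    last = None
    last_exc: Exception | None = None
    for method in methods:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit(reml=True, method=method, maxiter=500)
        except (np.linalg.LinAlgError, ValueError, OverflowError) as exc:
            last_exc = exc
            continue
        last = res
        if getattr(res, "converged", False):
            return res, True
    if last is None:
        raise last_exc if last_exc is not None else RuntimeError("fit failed")
    return last, False


def _extract_fe(result, backend: str, n: int, converged: bool) -> FitResult:
    params = result.fe_params if hasattr(result, "fe_params") else result.params
    bse = result.bse_fe if hasattr(result, "bse_fe") else result.bse
    pvals = result.pvalues
    coef = pd.DataFrame(
        {
            "estimate": params,
            "se": bse.reindex(params.index) if hasattr(bse, "reindex") else bse,
            "pvalue": pvals.reindex(params.index) if hasattr(pvals, "reindex") else pvals,
        }
    )
    coef = coef.loc[[i for i in coef.index if not str(i).endswith(" Var")]]
    return FitResult(coefficients=coef, backend=backend, converged=converged, n_rows=n)


def fit_ne_glmm(
    table: pd.DataFrame,
    backend: str = "lmm-log",
    pop_fixed: bool = False,
    replicate_sea_slope: bool = True,
) -> FitResult:
    """Mixed model of Ne on sea level x host category x time.

    Fixed effects are the full three-way interaction of ``sea_z``,
    ``host_category`` and ``time_z``; population enters as a random
    intercept within species by default (``pop_fixed=True`` adds it as a
    fixed effect too, the literal published formula, which is redundant
    with the random term).  Random effects are nested
    species / population / replicate intercepts.

    Backends: ``'lmm-log'`` (default) fits a linear mixed model on
    log(Ne) — the log-link correspondence of the Gamma GLMM — and, because
    interpolated trajectory values are strongly dependent within a
    replicate, additionally gives each replicate a random slope on
    ``sea_z`` (``replicate_sea_slope``) so that tests of sea-level effects
    are judged against between-replicate variation rather than the
    pseudo-replicated grid.  ``'glm-gamma'`` fits the fixed effects by a
    Gamma GLM with log link (no random effects), useful as a sign/scale
    cross-check.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    required = {"Ne", "log_ne", "sea_z", "time_z", "host_category", "species", "population", "replicate"}
    if not required <= set(table.columns):
        raise ValueError(f"model table missing columns {required - set(table.columns)}")
    if table["host_category"].nunique() < 2:
        raise ValueError("need at least 2 host categories")
    n = len(table)
    if np.ptp(table["log_ne"].to_numpy()) == 0.0:
        return FitResult(
            coefficients=pd.DataFrame(columns=["estimate", "se", "pvalue"]),
            backend=backend,
            converged=False,
            n_rows=n,
            notes="degenerate: response has zero variance",
        )
    fixed = "sea_z * C(host_category) * time_z"
    if pop_fixed:
        fixed += " + C(population)"

    if backend == "glm-gamma":
        model = smf.glm(
            f"Ne ~ {fixed}", data=table, family=sm.families.Gamma(sm.families.links.Log())
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit()
        return _extract_fe(res, backend, n, bool(res.converged))
    if backend != "lmm-log":
        raise ValueError(f"unknown backend {backend!r}")

    df = table.copy()
    df["rep_uid"] = df["population"].astype(str) + ":" + df["replicate"].astype(str)
    vc = {"pop": "0 + C(population)", "rep": "0 + C(rep_uid)"}
    if replicate_sea_slope:
        vc["rep_sea"] = "0 + C(rep_uid):sea_z"
    model = smf.mixedlm(
        f"log_ne ~ {fixed}",
        data=df,
        groups=df["species"],
        vc_formula=vc,
        re_formula="1",
    )
    try:
        res, converged = _fit_mixedlm(model)
    except (np.linalg.LinAlgError, ValueError) as exc:
        return FitResult(
            coefficients=pd.DataFrame(columns=["estimate", "se", "pvalue"]),
            backend=backend,
            converged=False,
            n_rows=n,
            notes=f"fit failed: {exc}",
        )
    out = _extract_fe(res, backend, n, converged)
    if replicate_sea_slope:
        out.notes = "replicate-level random slope on sea_z included"
    return out


@dataclass
class FanovaResult:
    """Pointwise F values, global statistic and permutation p-value."""

    pointwise_f: np.ndarray
    global_f: float
    p_value: float
    n_perm: int
    seed: int
    group_sizes: dict[str, int] = field(default_factory=dict)


def _pointwise_f(values: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """One-way F across groups at each grid column; NaN where any group has
    fewer than 2 covered trajectories."""
    k = len(groups)
    n_cols = values.shape[1]
    counts = np.zeros((k, n_cols))
    means = np.zeros((k, n_cols))
    ssw = np.zeros(n_cols)
    for gi, g in enumerate(groups):
        x = values[labels == g]
        cnt = np.sum(~np.isnan(x), axis=0)
        counts[gi] = cnt
        with np.errstate(invalid="ignore"):
            m = np.nansum(x, axis=0) / np.where(cnt > 0, cnt, np.nan)
        means[gi] = m
        ssw += np.nansum((x - m) ** 2, axis=0)
    valid = np.all(counts >= 2, axis=0)
    n_tot = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        grand = (counts * means).sum(axis=0) / n_tot
        ssb = (counts * (means - grand) ** 2).sum(axis=0)
        f = (ssb / (k - 1)) / (ssw / (n_tot - k))
    f[~valid] = np.nan
    return f


def functional_anova(
    ensemble: TrajectoryEnsemble,
    B: int = 999,
    seed: int = 0,
    group_col: str = "host_category",
) -> FanovaResult:
    """Permutation functional ANOVA of Ne trajectories between host groups.

    The pointwise one-way F statistic is computed at every grid point where
    each group has at least two covered trajectories; the global statistic
    is the mean pointwise F over those points.  Significance comes from
    permuting group labels *at the species level* (all trajectories of a
    species move together), with p = (1 + #{permuted >= observed})/(B + 1).
    Deterministic for a given seed.
    """
    labels = ensemble.meta[group_col].to_numpy()
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sizes = {g: int((labels == g).sum()) for g in groups}
    if min(sizes.values()) < 2:
        raise ValueError(f"every group needs >= 2 trajectories, got {sizes}")
    values = ensemble.values

    f_obs = _pointwise_f(values, labels, groups)
    if np.all(np.isnan(f_obs)):
        raise ValueError("no grid point has >= 2 covered trajectories per group")
    global_obs = float(np.nanmean(f_obs))

    species = ensemble.meta["species"].to_numpy()
    sp_unique, sp_index = np.unique(species, return_inverse=True)
    sp_labels = np.array(
        [labels[species == s][0] for s in sp_unique], dtype=object
    )
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(B):
        perm = rng.permutation(sp_labels)
        perm_labels = perm[sp_index]
        f_perm = _pointwise_f(values, perm_labels, groups)
        if np.nanmean(f_perm) >= global_obs:
            count += 1
    p = (1 + count) / (B + 1)
    return FanovaResult(
        pointwise_f=f_obs,
        global_f=global_obs,
        p_value=p,
        n_perm=B,
        seed=seed,
        group_sizes=sizes,
    )


def rank_sum_test(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney/Wilcoxon rank-sum; exact p when sample sizes allow.

    Returns (U statistic for the first sample, p-value).  Ties are handled
    by midranks (scipy falls back to the normal approximation then).
    """
    res = sps.mannwhitneyu(x, y, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def epoch_rank_tests(
    hm_table: pd.DataFrame,
    group_col: str = "host_category",
    value_col: str = "harmonic_mean_ne",
    epoch_col: str = "epoch",
    between_epoch_alternative: str = "two-sided",
) -> pd.DataFrame:
    """Rank tests on harmonic-mean Ne: across groups and between epochs.

    Per epoch, a Kruskal-Wallis test compares host groups; per group, a
    rank-sum test compares every (earlier, later) epoch pair in table
    order, with ``between_epoch_alternative`` applied as
    first-epoch-vs-second-epoch.  Rows with insufficient data are flagged
    ``'insufficient'`` rather than dropped.
    """
    rows = []
    epochs = list(pd.unique(hm_table[epoch_col]))
    for ep in epochs:
        sub = hm_table[hm_table[epoch_col] == ep]
        samples = [g[value_col].to_numpy() for _, g in sub.groupby(group_col)]
        names = [str(k) for k, _ in sub.groupby(group_col)]
        row = {
            "test": "kruskal_wallis",
            "epoch": ep,
            "epoch2": "",
            "group": "|".join(names),
            "statistic": np.nan,
            "df": len(samples) - 1,
            "pvalue": np.nan,
            "flag": "ok",
        }
        if len(samples) < 2 or any(len(s) < 2 for s in samples):
            row["flag"] = "insufficient"
        else:
            try:
                stat, p = sps.kruskal(*samples)
            except ValueError:  # all values identical
                stat, p = 0.0, 1.0
            if np.isnan(stat):  # fully tied data degenerates the statistic
                stat, p = 0.0, 1.0
            row["statistic"], row["pvalue"] = float(stat), float(p)
        rows.append(row)
    for grp, sub in hm_table.groupby(group_col):
        for i, ep1 in enumerate(epochs):
            for ep2 in epochs[i + 1 :]:
                x = sub.loc[sub[epoch_col] == ep1, value_col].to_numpy()
                y = sub.loc[sub[epoch_col] == ep2, value_col].to_numpy()
                row = {
                    "test": "rank_sum",
                    "epoch": ep1,
                    "epoch2": ep2,
                    "group": str(grp),
                    "statistic": np.nan,
                    "df": np.nan,
                    "pvalue": np.nan,
                    "flag": "ok",
                }
                if len(x) < 2 or len(y) < 2:
                    row["flag"] = "insufficient"
                else:
                    stat, p = rank_sum_test(x, y, alternative=between_epoch_alternative)
                    row["statistic"], row["pvalue"] = stat, p
                rows.append(row)
    return pd.DataFrame(rows)


def _check_design_rank(design: pd.DataFrame) -> None:
    x = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        bad = [design.columns[i] for i in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def adjust_pairwise(
    table: pd.DataFrame,
    value_col: str = "value",
    backend: str = "lmm",
) -> tuple[pd.DataFrame, FitResult]:
    """Remove distance and split-time effects from pairwise FST or dxy.

    Fits ``value ~ distance_z + splittime_z + host_category`` with crossed
    random intercepts for pop1 and pop2 and a random intercept for species
    (backend ``'lmm'``; ``'ols'`` drops the random structure), then
    subtracts the fitted distance and split-time contributions:
    ``adjusted = value - b_dist * distance_z - b_split * splittime_z``.
    Host-category and random-effect structure is deliberately retained in
    the adjusted values.
    """
    import statsmodels.formula.api as smf

    required = {"pop1", "pop2", "species", value_col, "distance_km", "split_time_years", "host_category"}
    if not required <= set(table.columns):
        raise ValueError(f"pairwise table missing columns {required - set(table.columns)}")
    if len(table) < 10 or table["species"].nunique() < 2:
        raise ValueError("need >= 10 pairs spanning >= 2 species")
    df = table.copy().reset_index(drop=True)
    df["distance_z"] = standardize(df["distance_km"].to_numpy())
    df["splittime_z"] = standardize(df["split_time_years"].to_numpy())

    design = pd.get_dummies(
        df[["distance_z", "splittime_z", "host_category"]],
        columns=["host_category"],
        drop_first=True,
        dtype=float,
    )
    design.insert(0, "Intercept", 1.0)
    _check_design_rank(design)

    formula = f"{value_col} ~ distance_z + splittime_z + C(host_category)"
    converged = True
    if backend == "lmm":
        vc = {"pop1": "0 + C(pop1)", "pop2": "0 + C(pop2)", "species": "0 + C(species)"}
        model = smf.mixedlm(
            formula, data=df, groups=np.ones(len(df)), vc_formula=vc, re_formula="0"
        )
        res, converged = _fit_mixedlm(model)
    elif backend == "ols":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.ols(formula, data=df).fit()
    else:
        raise ValueError(f"unknown backend {backend!r}")
    fit = _extract_fe(res, backend, len(df), converged)
    b_d = fit.coefficients.loc["distance_z", "estimate"]
    b_s = fit.coefficients.loc["splittime_z", "estimate"]
    df["adjusted"] = df[value_col] - b_d * df["distance_z"] - b_s * df["splittime_z"]
    return df, fit
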
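"""Per-plant viable seed dispersal and its drivers.

The number of viable seeds a frugivore disperses from a plant is estimated
multiplicatively from the interaction frequency and quality components:

    seeds(plant p, frugivore f) = visits_pf
                                  * feeding_rate_f      (cones / visit)
                                  * seeds_per_cone_p
                                  * undamaged_f         (gut passage survival)
                                  * viability_p         (viable-seed fraction)

e.g. five fox visits with feeding rate 7.4 cones/visit and 97% undamaged
seeds on a plant bearing 5.22 seeds/cone of 21% viability yield
5 * 7.4 * 5.22 * 0.97 * 0.21 = 39.3 viable seeds dispersed.

Downstream analyses: per-species shares of the pooled seed rain (with
bootstrap standard errors), a multiple regression of per-plant (log)
contributions on frugivore functional-group visits and reproductive traits
with AICc model selection and exact LMG relative-importance decomposition,
one-way ANOVA with Tukey-Kramer post hoc contrasts between modules/stands,
within-stand contribution z-scores and ranked cumulative-share curves, and
log-log regressions of contributions on plant size or network centrality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations, permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .matrix import VisitMatrix

__all__ = [
    "SeedRainTable",
    "estimate_dispersed_seeds",
    "species_shares",
    "bootstrap_species_totals",
    "contribution_regression",
    "aicc",
    "aicc_select",
    "lmg_importance",
    "group_anova_tukey",
    "stand_zscores",
    "plants_to_reach",
    "loglog_regression",
]


# ----------------------------------------------------------------------
# The estimator
# ----------------------------------------------------------------------

@dataclass
class SeedRainTable:
    """Estimated viable seeds dispersed, plants x species."""

    matrix: pd.DataFrame

    @property
    def plant_totals(self) -> pd.Series:
        return self.matrix.sum(axis=1)

    @property
    def species_totals(self) -> pd.Series:
        return self.matrix.sum(axis=0)

    @property
    def total(self) -> float:
        return float(self.matrix.to_numpy().sum())


def estimate_dispersed_seeds(visits: VisitMatrix, species: pd.DataFrame,
                             plants: pd.DataFrame) -> SeedRainTable:
    """Apply the multiplicative viable-seed estimator cell by cell.

    ``species`` needs columns species_id, feeding_rate, undamaged_fraction;
    ``plants`` needs plant_id, seeds_per_cone, seed_viability.  Every species
    and plant appearing in the visit matrix must be parameterized.
    """
    sp = species.set_index("species_id")
    pl = plants.set_index("plant_id")
    for s in visits.species:
        if s not in sp.index or sp.loc[s, ["feeding_rate",
                                           "undamaged_fraction"]].isna().any():
            raise ValueError(f"missing frugivore parameters for {s!r}")
    for p in visits.plants:
        if p not in pl.index or pl.loc[p, ["seeds_per_cone",
                                           "seed_viability"]].isna().any():
            raise ValueError(f"missing reproductive traits for plant {p!r}")
    fr = sp.loc[visits.species, "feeding_rate"].to_numpy(dtype=float)
    undamaged = sp.loc[visits.species, "undamaged_fraction"].to_numpy(float)
    seeds = pl.loc[visits.plants, "seeds_per_cone"].to_numpy(dtype=float)
    viability = pl.loc[visits.plants, "seed_viability"].to_numpy(dtype=float)
    S = visits.values * np.outer(seeds * viability, fr * undamaged)
    return SeedRainTable(pd.DataFrame(S, index=visits.plants,
                                      columns=visits.species))


def species_shares(table: SeedRainTable) -> pd.Series:
    """Each frugivore's share of the pooled seed rain (sums to 1)."""
    total = table.total
    if total <= 0:
        raise ValueError("zero pooled seed rain")
    return (table.species_totals / total).sort_values(ascending=False)


def bootstrap_species_totals(table: SeedRainTable, n_boot: int = 1000,
                             rng_seed: int = 0) -> pd.DataFrame:
    """Bootstrap standard errors of per-species seed totals.

    Resamples plants with replacement ``n_boot`` times and reports the
    standard deviation of the resampled species totals.
    """
    rng = np.random.default_rng(rng_seed)
    M = table.matrix.to_numpy()
    n = M.shape[0]
    totals = np.empty((n_boot, M.shape[1]))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        totals[b] = M[idx].sum(axis=0)
    return pd.DataFrame({
        "total": table.species_totals,
        "se": totals.std(axis=0, ddof=1),
    }, index=table.matrix.columns)


# ----------------------------------------------------------------------
# Contribution regression, AICc, LMG
# ----------------------------------------------------------------------

def build_regression_design(table: SeedRainTable, visits: VisitMatrix,
                            plants: pd.DataFrame, species: pd.DataFrame,
                            focal_species: str = "Turdus_philomelos"
                            ) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix and response for the contribution regression.

    Predictors per plant: visits by the focal (dominant) species on its own,
    visits by the remaining species pooled into functional groups (bird
    groups kept separate, mammal groups merged into ``mammals``), and the two
    reproductive traits (seeds per cone, seed viability).  Response:
    ``log(plant seed contribution + 1)``.
    """
    sp = species.set_index("species_id")

    def group_of(s):
        g = sp.loc[s, "functional_group"]
        return "mammals" if "mammal" in g else f"{g}s"

    X = pd.DataFrame(index=table.matrix.index)
    vis = visits.table
    if focal_species in vis.columns:
        X[focal_species] = vis[focal_species]
    groups = {}
    for s in vis.columns:
        if s == focal_species:
            continue
        groups.setdefault(group_of(s), []).append(s)
    for gname in sorted(groups):
        X[gname] = vis[groups[gname]].sum(axis=1)
    pl = plants.set_index("plant_id")
    X["seeds_per_cone"] = pl.loc[X.index, "seeds_per_cone"]
    X["seed_viability"] = pl.loc[X.index, "seed_viability"]
    y = np.log1p(table.plant_totals.loc[X.index]).rename("log_contribution")
    return X, y


@dataclass
class RegressionResult:
    params: pd.DataFrame       # estimate, se, t, p per term
    r_squared: float
    aicc: float
    n: int
    lmg: pd.Series | None = None
    selected: list = field(default_factory=list)


def _fit_ols(X: pd.DataFrame, y: pd.Series):
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy(dtype=float))
    if rank < design.shape[1]:
        aliased = [c for c in X.columns if X[c].std() == 0]
        raise ValueError(
            f"rank-deficient design (aliased columns, e.g. {aliased})")
    return sm.OLS(y, design).fit()


def aicc(fit) -> float:
    """Small-sample Akaike criterion for a Gaussian OLS fit.

    ``AICc = n log(RSS/n) + 2k + 2k(k+1)/(n - k - 1)`` with k counting all
    estimated parameters (coefficients including the intercept, plus the
    residual variance).
    """
    n = int(fit.nobs)
    rss = float(fit.ssr)
    k = int(fit.df_model) + 2  # slopes + intercept + variance
    if n - k - 1 <= 0:
        raise ValueError("too few observations for AICc")
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def contribution_regression(table: SeedRainTable, visits: VisitMatrix,
                            plants: pd.DataFrame, species: pd.DataFrame,
                            focal_species: str = "Turdus_philomelos",
                            compute_lmg: bool = True) -> RegressionResult:
    """OLS of log per-plant seed contributions on the standard predictor set.

    See :func:`build_regression_design` for the predictors.  Reports
    coefficient estimates with standard errors, t and p values, the model
    R², AICc and (optionally) LMG relative-importance shares.
    """
    X, y = build_regression_design(table, visits, plants, species,
                                   focal_species)
    fit = _fit_ols(X, y)
    params = pd.DataFrame({
        "estimate": fit.params, "se": fit.bse,
        "t": fit.tvalues, "p": fit.pvalues,
    })
    lmg = lmg_importance(X, y) if compute_lmg else None
    return RegressionResult(params=params, r_squared=float(fit.rsquared),
                            aicc=aicc(fit), n=int(fit.nobs), lmg=lmg,
                            selected=list(X.columns))


def aicc_select(X: pd.DataFrame, y: pd.Series,
                candidates=None) -> tuple[list, pd.DataFrame]:
    """All-subsets AICc model selection over the predictor columns.

    ``candidates`` may list explicit predictor subsets; by default all
    2^p - 1 nonempty subsets are enumerated (p <= 12).  Subsets with too few
    observations for the AICc correction are skipped with a warning.
    Returns (best subset, table of subsets with AICc ascending).
    """
    if candidates is None:
        cols = list(X.columns)
        if len(cols) > 12:
            raise ValueError("all-subsets enumeration limited to 12 predictors")
        candidates = [list(c) for r in range(1, len(cols) + 1)
                      for c in combinations(cols, r)]
    rows = []
    for subset in candidates:
        subset = list(subset)
        k = len(subset) + 2
        if len(y) - k - 1 <= 0:
            warnings.warn(f"subset {subset} skipped: too few observations")
            continue
        fit = _fit_ols(X[subset], y)
        rows.append((tuple(subset), aicc(fit), float(fit.rsquared)))
    if not rows:
        raise ValueError("no feasible candidate models")
    out = pd.DataFrame(rows, columns=["subset", "aicc", "r_squared"])
    out = out.sort_values("aicc", kind="mergesort").reset_index(drop=True)
    return list(out.loc[0, "subset"]), out


def _r2_cache(X: np.ndarray, y: np.ndarray):
    tss = ((y - y.mean()) ** 2).sum()
    cache: dict[frozenset, float] = {frozenset(): 0.0}

    def r2(subset: frozenset) -> float:
        if subset not in cache:
            cols = sorted(subset)
            design = np.column_stack([np.ones(len(y)), X[:, cols]])
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            rss = ((y - design @ coef) ** 2).sum()
            cache[subset] = 1.0 - rss / tss
        return cache[subset]

    return r2


def lmg_importance(X: pd.DataFrame, y: pd.Series,
                   by_permutation: bool = False) -> pd.Series:
    """LMG decomposition of R² into per-predictor shares.

    The share of predictor j is the average, over all orderings of the
    predictors, of the R² increase when j enters after its predecessors.
    Computed exactly through subset enumeration weighted by
    ``|S|! (p-|S|-1)! / p!`` (set ``by_permutation=True`` to average over
    explicit orderings instead — same result, only sensible for small p).
    Shares are nonnegative and sum to the full-model R².
    """
    cols = list(X.columns)
    p = len(cols)
    if p > 10:
        raise ValueError("exact LMG limited to 10 predictors")
    Xv = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), Xv])) < p + 1:
        raise ValueError("collinear predictors: R² decomposition ill-posed")
    yv = np.asarray(y, dtype=float)
    r2 = _r2_cache(Xv, yv)
    shares = np.zeros(p)
    if by_permutation:
        for order in permutations(range(p)):
            current: frozenset = frozenset()
            for j in order:
                nxt = current | {j}
                shares[j] += r2(nxt) - r2(current)
                current = nxt
        shares /= factorial(p)
    else:
        for j in range(p):
            others = [i for i in range(p) if i != j]
            for size in range(p):
                w = factorial(size) * factorial(p - size - 1) / factorial(p)
                for S in combinations(others, size):
                    S = frozenset(S)
                    shares[j] += w * (r2(S | {j}) - r2(S))
    return pd.Series(shares, index=cols)


# ----------------------------------------------------------------------
# Group comparisons
# ----------------------------------------------------------------------

@dataclass
class AnovaTukey:
    f_statistic: float
    df: tuple
    p: float
    r_squared: float
    group_means: pd.Series
    tukey: pd.DataFrame       # pairwise diff, se, q, p


def group_anova_tukey(values: pd.Series, groups: pd.Series,
                      log_transform: bool = True) -> AnovaTukey:
    """One-way ANOVA plus Tukey-Kramer pairwise comparisons.

    ``values`` are per-plant seed contributions (log(x+1)-transformed by
    default); ``groups`` assigns each plant to a module or stand.  Singleton
    groups are excluded with a warning.  Pairwise p-values use the
    studentized-range distribution with ``N - k`` degrees of freedom and the
    Tukey-Kramer standard error for unequal group sizes.
    """
    y = np.log1p(values.astype(float)) if log_transform else \
        values.astype(float)
    g = pd.Series(groups)
    sizes = g.value_counts()
    singles = sizes[sizes < 2].index.tolist()
    if singles:
        warnings.warn(f"singleton groups excluded: {singles}")
        keep = ~g.isin(singles)
        y, g = y[keep.to_numpy()], g[keep]
    levels = sorted(g.unique())
    k = len(levels)
    if k < 2:
        raise ValueError("need at least two groups of size >= 2")
    n = len(y)
    grand = y.mean()
    means = y.groupby(g.to_numpy()).mean()
    ss_between = sum(sizes[lv] * (means[lv] - grand) ** 2 for lv in levels)
    ss_within = sum(((y[(g == lv).to_numpy()] - means[lv]) ** 2).sum()
                    for lv in levels)
    df_b, df_w = k - 1, n - k
    mse = ss_within / df_w
    f_stat = (ss_between / df_b) / mse
    p = float(stats.f.sf(f_stat, df_b, df_w))
    rows = []
    for a, b in combinations(levels, 2):
        diff = means[a] - means[b]
        se = np.sqrt(mse / 2.0 * (1.0 / sizes[a] + 1.0 / sizes[b]))
        q = abs(diff) / se
        rows.append((a, b, float(diff), float(se), float(q),
                     float(stats.studentized_range.sf(q, k, df_w))))
    tukey = pd.DataFrame(rows, columns=["group_a", "group_b", "diff",
                                        "se", "q", "p"])
    return AnovaTukey(
        f_statistic=float(f_stat), df=(df_b, df_w), p=p,
        r_squared=float(ss_between / (ss_between + ss_within)),
        group_means=means, tukey=tukey)


# ----------------------------------------------------------------------
# Within-stand contribution inequality
# ----------------------------------------------------------------------

def stand_zscores(table: SeedRainTable, plants: pd.DataFrame) -> pd.DataFrame:
    """Within-stand z-scores and ranked cumulative-share curves.

    Per plant: its stand, seed contribution, z-score against the stand mean
    (sample s.d.), descending rank within the stand and the cumulative share
    of the stand's seed rain accounted for down to that rank.
    """
    contrib = table.plant_totals
    out = plants[["plant_id", "stand"]].copy()
    out["contribution"] = contrib.loc[out["plant_id"]].to_numpy()
    frames = []
    for stand, grp in out.groupby("stand", sort=False):
        if len(grp) < 2:
            raise ValueError(f"stand {stand!r} needs at least two plants")
        if grp["contribution"].sum() <= 0:
            raise ValueError(f"stand {stand!r} has zero total seed rain")
        sd = grp["contribution"].std(ddof=1)
        grp = grp.sort_values("contribution", ascending=False,
                              kind="mergesort").copy()
        if sd == 0:
            warnings.warn(f"stand {stand!r} has zero contribution spread; "
                          "z-scores set to 0")
            grp["z"] = 0.0
        else:
            grp["z"] = (grp["contribution"] - grp["contribution"].mean()) / sd
        grp["rank"] = np.arange(1, len(grp) + 1)
        grp["cumulative_share"] = (grp["contribution"].cumsum()
                                   / grp["contribution"].sum())
        frames.append(grp)
    return pd.concat(frames, ignore_index=True)


def plants_to_reach(ranking: pd.DataFrame, share: float = 0.5) -> pd.Series:
    """Plants needed to accumulate ``share`` of each stand's seed rain.

    A small number marks a truncated, unequal contribution curve (few
    super-spreader plants)."""
    out = {}
    for stand, grp in ranking.groupby("stand", sort=False):
        reached = grp.loc[grp["cumulative_share"] >= share, "rank"]
        out[stand] = int(reached.min())
    return pd.Series(out, name=f"plants_to_{share:.0%}")


def loglog_regression(values: pd.Series, covariate: pd.Series,
                      add_one: bool = True) -> RegressionResult:
    """Simple OLS of log contributions on a log-transformed covariate.

    ``values`` get a +1 guard before the log by default (plants can have a
    zero estimated contribution); the covariate must be strictly positive.
    """
    x = covariate.astype(float)
    if (x <= 0).any():
        raise ValueError("covariate must be positive for the log transform")
    y = np.log1p(values.astype(float)) if add_one \
        else np.log(values.astype(float))
    X = pd.DataFrame({"log_" + (covariate.name or "covariate"): np.log(x)})
    fit = _fit_ols(X, y)
    params = pd.DataFrame({
        "estimate": fit.params, "se": fit.bse,
        "t": fit.tvalues, "p": fit.pvalues,
    })
    return RegressionResult(params=params, r_squared=float(fit.rsquared),
                            aicc=aicc(fit), n=int(fit.nobs),
                            selected=list(X.columns))
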
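"""Seed-rain estimation, regression machinery and contribution rankings."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from frugnet import (SeedRainTable, VisitMatrix, aicc, aicc_select,
                     estimate_dispersed_seeds, group_anova_tukey,
                     lmg_importance, loglog_regression, plants_to_reach,
                     species_shares, stand_zscores)
from frugnet.seedrain import _fit_ols

from .oracles import ols_r2


def _tiny_system(visits=5.0, fr=7.4, seeds=5.22, undamaged=0.97,
                 viability=0.21):
    vm = VisitMatrix(pd.DataFrame([[visits]], index=["C106"],
                                  columns=["fox"]))
    species = pd.DataFrame({"species_id": ["fox"], "feeding_rate": [fr],
                            "undamaged_fraction": [undamaged]})
    plants = pd.DataFrame({"plant_id": ["C106"], "seeds_per_cone": [seeds],
                           "seed_viability": [viability]})
    return vm, species, plants


def test_multiplicative_estimator_worked_example():
    """5 visits x 7.4 cones/visit x 5.22 seeds/cone x 0.97 undamaged x 0.21
    viable = 39.3 viable seeds dispersed."""
    table = estimate_dispersed_seeds(*_tiny_system())
    assert round(float(table.matrix.iloc[0, 0]), 1) == 39.3


def test_zero_viability_annihilates():
    table = estimate_dispersed_seeds(*_tiny_system(viability=0.0))
    assert table.total == 0.0


def test_estimator_is_multilinear():
    base = estimate_dispersed_seeds(*_tiny_system()).total
    assert estimate_dispersed_seeds(*_tiny_system(visits=10.0)).total == \
        pytest.approx(2 * base)
    assert estimate_dispersed_seeds(*_tiny_system(fr=3.7)).total == \
        pytest.approx(base / 2)


def test_missing_parameters_named():
    vm, species, plants = _tiny_system()
    with pytest.raises(ValueError, match="fox"):
        estimate_dispersed_seeds(vm, species.assign(feeding_rate=np.nan),
                                 plants)
    with pytest.raises(ValueError, match="C106"):
        estimate_dispersed_seeds(vm, species,
                                 plants.assign(seed_viability=np.nan))


def test_species_shares_hand_arithmetic():
    table = SeedRainTable(pd.DataFrame([[30.0, 10.0], [30.0, 30.0]],
                                       columns=["a", "b"]))
    shares = species_shares(table)
    assert shares["a"] == pytest.approx(0.6)
    assert shares["b"] == pytest.approx(0.4)
    assert shares.sum() == pytest.approx(1.0)
    single = SeedRainTable(pd.DataFrame([[5.0]], columns=["only"]))
    assert species_shares(single)["only"] == 1.0


# ----------------------------------------------------------------------
# AICc
# ----------------------------------------------------------------------

def test_aicc_formula_and_correction_positive():
    rng = np.random.default_rng(0)
    X = pd.DataFrame({"x": rng.normal(size=40)})
    y = pd.Series(2 * X["x"] + rng.normal(size=40))
    fit = _fit_ols(X, y)
    n, k = 40, 3  # slope + intercept + variance
    expected = n * np.log(fit.ssr / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    assert aicc(fit) == pytest.approx(expected)
    aic = n * np.log(fit.ssr / n) + 2 * k
    assert aicc(fit) > aic


def test_aicc_selection_recovers_true_subset():
    """The true model, nested among competing candidate models, wins on
    AICc with strong signal at n = 105 in >= 90% of replicates."""
    rng = np.random.default_rng(1)
    candidates = [["a"], ["c"], ["b"], ["a", "b"], ["c", "e"],
                  ["b", "d", "e"], ["a", "c"]]
    hits = 0
    for rep in range(20):
        X = pd.DataFrame(rng.normal(size=(105, 5)),
                         columns=list("abcde"))
        y = 2.0 * X["a"] - 1.5 * X["c"] + rng.normal(0, 1.0, 105)
        best, table = aicc_select(X, pd.Series(y), candidates=candidates)
        hits += int(set(best) == {"a", "c"})
    assert hits >= 18  # >= 90 %
    # all-subsets default: best model must at least contain the signal
    best_all, _ = aicc_select(X, pd.Series(y))
    assert {"a", "c"} <= set(best_all)
    # determinism: identical candidate subsets give identical AICc
    _, t2 = aicc_select(X, pd.Series(y), candidates=[["a", "c"], ["a", "c"]])
    assert t2["aicc"].nunique() == 1


# ----------------------------------------------------------------------
# LMG
# ----------------------------------------------------------------------

def test_lmg_single_predictor_share_is_r_squared():
    rng = np.random.default_rng(2)
    X = pd.DataFrame({"x": rng.normal(size=50)})
    y = pd.Series(X["x"] + rng.normal(0, 0.5, 50))
    shares = lmg_importance(X, y)
    assert shares["x"] == pytest.approx(
        ols_r2(X.to_numpy(), y.to_numpy(), [0]))


def test_lmg_orthogonal_predictors_get_marginal_r2():
    rng = np.random.default_rng(3)
    raw = rng.normal(size=(80, 3))
    Q, _ = np.linalg.qr(raw - raw.mean(axis=0))  # centered & orthogonal
    X = pd.DataFrame(Q, columns=list("abc"))
    y = pd.Series(1.0 * Q[:, 0] + 0.5 * Q[:, 1] + 0.1 * rng.normal(size=80))
    shares = lmg_importance(X, y)
    for j, v in enumerate("abc"):
        assert shares[v] == pytest.approx(
            ols_r2(Q, y.to_numpy(), [j]), abs=1e-10)


@pytest.mark.parametrize("p", [3, 4, 5, 6])
def test_lmg_subset_formula_equals_ordering_average(p):
    """The combinatorial subset formula must agree with direct averaging
    over all p! entry orderings, and shares must sum to the model R2."""
    rng = np.random.default_rng(p)
    base = rng.normal(size=(60, p))
    X = pd.DataFrame(base + 0.5 * base[:, [0]],  # induce correlation
                     columns=[f"v{j}" for j in range(p)])
    y = pd.Series(X.to_numpy() @ rng.uniform(0.2, 1.0, p)
                  + rng.normal(size=60))
    fast = lmg_importance(X, y)
    slow = lmg_importance(X, y, by_permutation=True)
    assert np.allclose(fast, slow, atol=1e-10)
    full_r2 = ols_r2(X.to_numpy(), y.to_numpy(), list(range(p)))
    assert fast.sum() == pytest.approx(full_r2, abs=1e-8)
    assert (fast >= -1e-12).all()


def test_lmg_rejects_collinear_design():
    rng = np.random.default_rng(4)
    X = pd.DataFrame({"a": rng.normal(size=30)})
    X["b"] = 2 * X["a"]
    with pytest.raises(ValueError):
        lmg_importance(X, pd.Series(rng.normal(size=30)))


# ----------------------------------------------------------------------
# ANOVA + Tukey
# ----------------------------------------------------------------------

def test_anova_f_matches_hand_computation():
    values = pd.Series([1.0, 2, 3, 4, 5, 6, 7, 8, 9], dtype=float)
    groups = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
    res = group_anova_tukey(values, groups, log_transform=False)
    # group means 2, 5, 8; grand 5; SSB = 3*(9+0+9) = 54; SSW = 6; df (2, 6)
    assert res.f_statistic == pytest.approx((54 / 2) / (6 / 6))
    assert res.df == (2, 6)
    assert res.r_squared == pytest.approx(54 / 60)


def test_extreme_group_shift_is_significant():
    rng = np.random.default_rng(5)
    values = pd.Series(np.concatenate([
        rng.normal(0, 1, 20), rng.normal(0, 1, 20),
        rng.normal(10, 1, 20)]))
    groups = pd.Series(np.repeat(["a", "b", "c"], 20))
    res = group_anova_tukey(values, groups, log_transform=False)
    tuk = res.tukey.set_index(["group_a", "group_b"])
    assert tuk.loc[("a", "c"), "p"] < 1e-6
    assert tuk.loc[("b", "c"), "p"] < 1e-6
    assert tuk.loc[("a", "b"), "p"] > 0.05


def test_tukey_type_one_error_near_nominal():
    """Identical populations: family-wise rejection rate ~ alpha."""
    rng = np.random.default_rng(6)
    rejections = 0
    reps = 400
    for _ in range(reps):
        values = pd.Series(rng.normal(size=30))
        groups = pd.Series(np.repeat(["a", "b", "c"], 10))
        res = group_anova_tukey(values, groups, log_transform=False)
        rejections += int((res.tukey["p"] < 0.05).any())
    rate = rejections / reps
    se = np.sqrt(0.05 * 0.95 / reps)
    assert abs(rate - 0.05) < 4 * se


def test_studentized_range_against_published_table():
    """q(0.95; k=3, df=10) = 3.88 and q(0.95; k=4, df=20) = 3.96 (standard
    studentized-range tables, 2 dp)."""
    assert stats.studentized_range.ppf(0.95, 3, 10) == \
        pytest.approx(3.88, abs=0.01)
    assert stats.studentized_range.ppf(0.95, 4, 20) == \
        pytest.approx(3.96, abs=0.01)


def test_singleton_group_excluded_with_warning():
    values = pd.Series([1.0, 2, 3, 4, 5, 6, 7])
    groups = pd.Series(["a", "a", "a", "b", "b", "b", "c"])
    with pytest.warns(UserWarning, match="singleton"):
        res = group_anova_tukey(values, groups, log_transform=False)
    assert set(res.group_means.index) == {"a", "b"}


# ----------------------------------------------------------------------
# Rankings and simple regressions
# ----------------------------------------------------------------------

def _ranking_fixture():
    table = SeedRainTable(pd.DataFrame(
        {"sp": [100.0, 10.0, 10.0, 5.0, 5.0, 5.0]},
        index=[f"p{i}" for i in range(6)]))
    plants = pd.DataFrame({
        "plant_id": [f"p{i}" for i in range(6)],
        "stand": ["A", "A", "A", "B", "B", "B"]})
    return table, plants


def test_zscores_center_and_cumulative_shares():
    table, plants = _ranking_fixture()
    ranking = stand_zscores(table, plants)
    for _, grp in ranking.groupby("stand"):
        assert grp["z"].sum() == pytest.approx(0.0, abs=1e-10)
        assert grp["cumulative_share"].iloc[-1] == pytest.approx(1.0)
    top_a = ranking[ranking["stand"] == "A"].iloc[0]
    assert top_a["cumulative_share"] == pytest.approx(100 / 120)
    n50 = plants_to_reach(ranking, 0.5)
    assert n50["A"] == 1   # one dominant plant reaches half the stand rain
    assert n50["B"] == 2   # equal contributors: need two of three


def test_equal_contributions_give_zero_z_with_warning():
    table = SeedRainTable(pd.DataFrame({"sp": [5.0, 5.0]},
                                       index=["p0", "p1"]))
    plants = pd.DataFrame({"plant_id": ["p0", "p1"], "stand": ["A", "A"]})
    with pytest.warns(UserWarning, match="zero contribution spread"):
        ranking = stand_zscores(table, plants)
    assert (ranking["z"] == 0).all()


def test_loglog_recovers_power_law():
    x = pd.Series(np.linspace(1, 50, 40), name="cover")
    y = x ** 2
    res = loglog_regression(y, x, add_one=False)
    assert res.params.loc["log_cover", "estimate"] == pytest.approx(2.0)
    assert res.r_squared == pytest.approx(1.0)


def test_loglog_slope_invariant_to_covariate_scaling():
    rng = np.random.default_rng(7)
    x = pd.Series(rng.uniform(1, 30, 50), name="cover")
    y = pd.Series(x ** 1.5 * rng.lognormal(0, 0.2, 50))
    a = loglog_regression(y, x)
    b = loglog_regression(y, 10 * x)
    assert a.params.iloc[1]["estimate"] == \
        pytest.approx(b.params.iloc[1]["estimate"])
    assert a.r_squared == pytest.approx(b.r_squared)


def test_loglog_permutation_null_r2_near_zero():
    rng = np.random.default_rng(8)
    x = pd.Series(rng.uniform(1, 30, 100), name="cover")
    y = pd.Series(x ** 2)
    r2 = [loglog_regression(pd.Series(rng.permutation(y.to_numpy())),
                            x).r_squared for _ in range(50)]
    assert np.mean(r2) < 0.05


def test_nonpositive_covariate_rejected():
    with pytest.raises(ValueError):
        loglog_regression(pd.Series([1.0, 2.0]),
                          pd.Series([0.0, 1.0], name="cover"))
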
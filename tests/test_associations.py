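"""Spearman screens, regression, ANOVA, Duncan letters, t-tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from mpcommunity import (
    StatisticalError,
    duncan_letters,
    independent_t_test,
    one_way_anova,
    simple_regression,
    spearman_screen,
    studentized_range_quantile,
)
from mpcommunity.associations import spearman_rho

# upper-5% studentized range critical values, frozen from R's qtukey
# (independent of the scipy distribution used by the implementation)
QTUKEY_05 = {
    (2, 5): 3.6354, (2, 10): 3.1511, (2, 15): 3.0143, (2, 20): 2.9500,
    (2, 30): 2.8882, (3, 5): 4.6017, (3, 10): 3.8768, (3, 15): 3.6734,
    (3, 20): 3.5779, (3, 30): 3.4864, (4, 5): 5.2183, (4, 10): 4.3266,
    (4, 15): 4.0760, (4, 20): 3.9583, (4, 30): 3.8454, (5, 5): 5.6731,
    (5, 10): 4.6543, (5, 15): 4.3670, (5, 20): 4.2319, (5, 30): 4.1021,
    (6, 5): 6.0329, (6, 10): 4.9120, (6, 15): 4.5947, (6, 20): 4.4452,
    (6, 30): 4.3015, (8, 5): 6.5823, (8, 10): 5.3042, (8, 15): 4.9399,
    (8, 20): 4.7676, (8, 30): 4.6014, (10, 5): 6.9947, (10, 10): 5.5984,
    (10, 15): 5.1979, (10, 20): 5.0079, (10, 30): 4.8241,
}


# ----------------------------------------------------------------- Spearman

def test_spearman_monotone_extremes():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    assert spearman_rho(x, np.exp(x)) == pytest.approx(1.0)
    assert spearman_rho(x, -(x**3)) == pytest.approx(-1.0)


def test_spearman_with_ties_equals_pearson_on_midranks(rng):
    x = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 4.0])
    y = rng.random(6)
    oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
    assert spearman_rho(x, y) == pytest.approx(float(oracle))


@given(st.integers(0, 50))
def test_spearman_invariant_under_monotone_transforms(seed):
    rng = np.random.default_rng(seed)
    x = rng.random(12)
    y = rng.random(12)
    base = spearman_rho(x, y)
    assert spearman_rho(np.exp(3 * x), y) == pytest.approx(base)
    assert spearman_rho(x, y**3) == pytest.approx(base)


def test_spearman_screen_shapes_and_flags():
    idx = [f"s{i}" for i in range(12)]
    rng = np.random.default_rng(0)
    metrics = pd.DataFrame({"m1": rng.random(12), "m2": rng.random(12)}, index=idx)
    cov = pd.DataFrame(
        {"c1": rng.random(12), "sparse": [np.nan] * 10 + [1.0, 2.0]}, index=idx
    )
    screen = spearman_screen(metrics, cov)
    assert screen.rho.shape == (2, 2)
    # the sparse covariate has only 2 complete pairs -> flagged not-estimable
    assert screen.n.loc["m1", "sparse"] == 2
    assert np.isnan(screen.rho.loc["m1", "sparse"])
    assert np.isnan(screen.q.loc["m1", "sparse"])
    # BH q is never below raw p on estimable cells
    assert ((screen.q >= screen.p - 1e-12) | screen.p.isna()).all().all()


def test_spearman_screen_exact_small_n_matches_scipy_exact():
    idx = [f"s{i}" for i in range(7)]
    rng = np.random.default_rng(3)
    x = rng.random(7)
    y = rng.random(7)
    screen = spearman_screen(
        pd.DataFrame({"m": x}, index=idx), pd.DataFrame({"c": y}, index=idx)
    )
    # scipy's small-n method differs slightly from the two-sided
    # permutation p; they must agree closely but not exactly
    rho_s, p_s = stats.spearmanr(x, y)
    assert screen.rho.loc["m", "c"] == pytest.approx(float(rho_s))
    assert screen.p.loc["m", "c"] == pytest.approx(float(p_s), abs=0.05)


# --------------------------------------------------------------- regression

def test_regression_perfect_line():
    x = np.array([0.0, 1.0, 2.0, 3.0])
    res = simple_regression(x, 2 * x + 1)
    assert res.slope == pytest.approx(2.0)
    assert res.intercept == pytest.approx(1.0)
    assert res.r == pytest.approx(1.0)
    assert res.p_value < 1e-6


def test_regression_r_squared_identity(rng):
    x = rng.random(20)
    y = 3 * x + rng.normal(0, 0.5, 20)
    res = simple_regression(x, y)
    ss_res = np.sum((y - res.intercept - res.slope * x) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    assert res.r**2 == pytest.approx(1 - ss_res / ss_tot)
    assert np.sign(res.r) == np.sign(res.slope)


def test_regression_constant_x_is_error():
    with pytest.raises(StatisticalError):
        simple_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_planted_slope_recovered_within_ci():
    # generator with a planted abundance~population slope; the OLS point
    # estimate must land inside its own analytic 95% CI about 95% of the
    # time (spot version of the acceptance-scale run)
    from mpcommunity import perturb_config, simulate_survey, summarize_samples
    from mpcommunity.synthetic import null_config

    beta = 2.0
    cover = 0
    n_seeds = 60
    for seed in range(n_seeds):
        config = perturb_config(null_config(), "population_slope", beta)
        bundle = simulate_survey(config, seed=seed)
        summary = summarize_samples(bundle.particles, bundle.meta)
        pop = bundle.covariates["population"]
        res = simple_regression(pop, summary["abundance"].loc[pop.index])
        se = (
            np.sqrt(
                np.sum(
                    (summary["abundance"].loc[pop.index] - res.intercept
                     - res.slope * pop) ** 2
                )
                / (res.n - 2)
            )
            / np.sqrt(np.sum((pop - pop.mean()) ** 2))
        )
        t_crit = stats.t.ppf(0.975, res.n - 2)
        cover += abs(res.slope - beta) <= t_crit * se
    assert cover / n_seeds >= 0.85


# -------------------------------------------------------------------- ANOVA

def test_anova_hand_value():
    f, p = one_way_anova(
        [1, 2, 3, 4, 5, 6, 7, 8, 9],
        ["a", "a", "a", "b", "b", "b", "c", "c", "c"],
    )
    assert f == pytest.approx(27.0)
    assert p == pytest.approx(stats.f.sf(27.0, 2, 6))


def test_two_group_anova_equals_t_squared(rng):
    a = rng.normal(size=8)
    b = rng.normal(size=6)
    values = np.concatenate([a, b])
    groups = ["a"] * 8 + ["b"] * 6
    f, p_f = one_way_anova(values, groups)
    t, p_t = independent_t_test(a, b, variance_policy="pooled")
    assert f == pytest.approx(t**2, abs=1e-9)
    assert p_f == pytest.approx(p_t, abs=1e-9)


def test_anova_singleton_group_is_error():
    with pytest.raises(StatisticalError):
        one_way_anova([1, 2, 3], ["a", "a", "b"])


# ----------------------------------------------------------- Duncan letters

def test_studentized_range_quantiles_match_published_table():
    for (p, df), expected in QTUKEY_05.items():
        assert studentized_range_quantile(0.05, p, df) == pytest.approx(
            expected, abs=0.01
        )


def test_well_separated_means_get_distinct_letters(rng):
    # tiny within-group noise: every group separated
    values, groups = [], []
    for i, mu in enumerate([0.0, 10.0, 20.0, 30.0]):
        values += list(mu + 1e-6 * rng.standard_normal(3))
        groups += [f"g{i}"] * 3
    res = duncan_letters(values, groups)
    letters = list(res.letters.values())
    assert len(set(letters)) == 4
    assert all(len(l) == 1 for l in letters)


def test_identical_data_shares_one_letter():
    res = duncan_letters([5.0] * 9, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
    assert set(res.letters.values()) == {"a"}


def test_two_group_duncan_matches_pooled_t(rng):
    # k = 2: Duncan separation iff pooled t-test rejects at alpha
    for seed in range(30):
        r = np.random.default_rng(seed)
        a = r.normal(0, 1, 5)
        b = r.normal(r.uniform(0, 2), 1, 5)
        res = duncan_letters(np.concatenate([a, b]), ["a"] * 5 + ["b"] * 5)
        separated = res.letters["a"] != res.letters["b"]
        _, p = independent_t_test(a, b, variance_policy="pooled")
        assert separated == (p < 0.05)


def test_letters_are_order_consistent(rng):
    # if i and j share a letter, every group with mean in between shares
    # a letter with both
    for seed in range(20):
        r = np.random.default_rng(100 + seed)
        values, groups = [], []
        for i in range(5):
            values += list(r.normal(r.uniform(0, 3), 1.0, 4))
            groups += [f"g{i}"] * 4
        res = duncan_letters(values, groups)
        means, letters = res.means, res.letters
        names = sorted(means, key=means.get)
        for i, gi in enumerate(names):
            for j in range(i + 2, len(names)):
                gj = names[j]
                if set(letters[gi]) & set(letters[gj]):
                    for gm in names[i + 1:j]:
                        assert set(letters[gm]) & set(letters[gi])
                        assert set(letters[gm]) & set(letters[gj])


# ------------------------------------------------------------------ t-tests

def test_t_test_identical_samples():
    t, p = independent_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_t_test_textbook_pooled_value():
    t, _ = independent_t_test([1, 2, 3, 4], [3, 4, 5, 6], variance_policy="pooled")
    assert t == pytest.approx(-2.191, abs=5e-4)


def test_t_test_null_calibration():
    rng = np.random.default_rng(99)
    rej = 0
    n_sims = 1000
    for _ in range(n_sims):
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        _, p = independent_t_test(a, b)
        rej += p <= 0.05
    assert 0.03 <= rej / n_sims <= 0.07


def test_t_test_small_sample_is_error():
    with pytest.raises(StatisticalError):
        independent_t_test([1.0], [1.0, 2.0])
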
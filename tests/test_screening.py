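"""t test, chi-square, Bonferroni rule and the logistic factor screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from glaucoma_claims.screening import (
    StatsConfig,
    TTestVariant,
    bonferroni_significant,
    chi_square_2x2,
    stepwise_logistic,
    two_sample_t,
    univariate_screen,
)


# ------------------------------------------------------------------- t test


def test_t_identical_groups():
    t, _, p = two_sample_t(10.0, 2.0, 50, 10.0, 2.0, 50)
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_t_matches_direct_formula():
    """Pooled-variance Student's t recomputed from the textbook formula."""
    m1, s1, n1, m2, s2, n2 = 5.1, 1.2, 14, 4.3, 1.5, 11
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    t_direct = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    t, df, _ = two_sample_t(m1, s1, n1, m2, s2, n2)
    assert t == pytest.approx(t_direct, abs=1e-10)
    assert df == n1 + n2 - 2


def test_t_welch_variant_differs():
    args = (10.0, 1.0, 20, 11.0, 5.0, 100)
    _, df_p, p_pooled = two_sample_t(*args, TTestVariant.POOLED)
    _, df_w, p_welch = two_sample_t(*args, TTestVariant.WELCH)
    assert df_w != df_p and p_welch != p_pooled


def test_t_published_cohort_summary():
    """Printed cohort means/SDs give a p value near the published 0.5131
    (exact match is impossible from rounded inputs)."""
    _, _, p = two_sample_t(60.9, 34.0, 1183, 59.7, 35.8, 542)
    assert p == pytest.approx(0.5131, abs=0.02)


def test_t_rejects_tiny_groups():
    with pytest.raises(ValueError):
        two_sample_t(1, 1, 1, 2, 1, 10)


# --------------------------------------------------------------- chi-square


@pytest.mark.parametrize(
    "table, expected_p",
    [((483, 700, 235, 307), 0.3225), ((76, 113, 71, 56), 0.0061)],
)
def test_chi_square_reproduces_published_p_values(table, expected_p):
    _, p = chi_square_2x2(*table)
    assert round(p, 4) == expected_p


def test_chi_square_independent_table():
    chi2, p = chi_square_2x2(10, 10, 10, 10)
    assert chi2 == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_chi_square_zero_margin_rejected():
    with pytest.raises(ValueError):
        chi_square_2x2(0, 0, 5, 5)


def test_chi_square_row_column_swap_invariance():
    ref, _ = chi_square_2x2(12, 7, 4, 19)
    swapped_rows, _ = chi_square_2x2(4, 19, 12, 7)
    swapped_cols, _ = chi_square_2x2(7, 12, 19, 4)
    assert swapped_rows == pytest.approx(ref)
    assert swapped_cols == pytest.approx(ref)


@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.tuples(*[st.integers(1, 200)] * 4))
def test_chi_square_equals_squared_two_proportion_z(cells):
    """Algebraic identity: the squared two-proportion z statistic is the
    uncorrected Pearson chi-square."""
    a, b, c, d = cells
    chi2, _ = chi_square_2x2(a, b, c, d)
    p1, p2 = a / (a + b), c / (c + d)
    p_pool = (a + c) / (a + b + c + d)
    z = (p1 - p2) / np.sqrt(p_pool * (1 - p_pool) * (1 / (a + b) + 1 / (c + d)))
    assert z**2 == pytest.approx(chi2, rel=1e-9)


def test_yates_correction_changes_subset_p():
    _, p_plain = chi_square_2x2(76, 113, 71, 56)
    _, p_yates = chi_square_2x2(76, 113, 71, 56, continuity_correction=True)
    assert round(p_plain, 4) == 0.0061
    assert p_yates > p_plain  # the corrected value would not match print


# --------------------------------------------------------------- Bonferroni


def test_bonferroni_threshold_and_boundary():
    cfg = StatsConfig()
    assert cfg.bonferroni_threshold == pytest.approx(0.05 / 6)
    assert bonferroni_significant(0.0061, cfg)
    assert not bonferroni_significant(0.05 / 6, cfg)  # strict inequality
    assert not bonferroni_significant(0.05, StatsConfig(m_tests=1))


# ------------------------------------------------------------ factor screen


def _simulate_covariates(rng, n, beta=0.0):
    x = rng.normal(0, 1, n)
    logit = -1.5 + beta * x
    y = rng.random(n) < 1 / (1 + np.exp(-logit))
    return pd.Series(x), pd.Series(y.astype(int))


def test_separation_is_flagged():
    y = pd.Series([0, 0, 0, 1, 1, 1] * 10)
    cov = pd.DataFrame({"mirror": y.astype(float)})
    with pytest.warns(UserWarning, match="separation"):
        results = univariate_screen(cov, y)
    assert results[0].separation_flag and not results[0].passed_screen


def test_screen_handles_missing_values_complete_case():
    rng = np.random.default_rng(0)
    x, y = _simulate_covariates(rng, 500, beta=1.0)
    x[::3] = np.nan
    results = univariate_screen(pd.DataFrame({"x": x}), y)
    assert results[0].n_used == int(x.notna().sum())
    assert results[0].passed_screen


def test_or_recovery_single_replicate():
    rng = np.random.default_rng(3)
    true_or = 1.5
    x, y = _simulate_covariates(rng, 5000, beta=np.log(true_or))
    cov = pd.DataFrame({"x": x})
    screened = univariate_screen(cov, y)
    final = stepwise_logistic(cov, y, screened)
    (res,) = final
    assert res.in_final_model
    assert res.ci_low < true_or < res.ci_high
    assert res.odds_ratio == pytest.approx(true_or, rel=0.2)


def test_one_factor_stepwise_reduces_to_univariate():
    rng = np.random.default_rng(4)
    x, y = _simulate_covariates(rng, 2000, beta=0.5)
    cov = pd.DataFrame({"x": x})
    screened = univariate_screen(cov, y)
    final = stepwise_logistic(cov, y, screened)
    # a lone factor's multivariate fit is the univariate fit
    assert final[0].in_final_model == screened[0].passed_screen
    import statsmodels.api as sm

    fit = sm.Logit(y.to_numpy(), sm.add_constant(x.to_numpy())).fit(disp=0)
    assert final[0].odds_ratio == pytest.approx(float(np.exp(fit.params[1])), rel=1e-6)


def test_stepwise_selects_true_factor_among_nulls():
    rng = np.random.default_rng(6)
    n = 3000
    hits = 0
    for _ in range(10):
        x_true, y = _simulate_covariates(rng, n, beta=np.log(2.0))
        cov = pd.DataFrame({"signal": x_true})
        for j in range(5):
            cov[f"noise{j}"] = rng.normal(0, 1, n)
        final = stepwise_logistic(cov, y, univariate_screen(cov, y))
        by_name = {r.factor: r for r in final}
        hits += by_name["signal"].in_final_model
    assert hits >= 9


def test_all_null_factors_usually_give_empty_model():
    rng = np.random.default_rng(7)
    n_selected = 0
    for _ in range(10):
        y = pd.Series((rng.random(1000) < 0.3).astype(int))
        cov = pd.DataFrame({f"n{j}": rng.normal(0, 1, 1000) for j in range(3)})
        final = stepwise_logistic(cov, y, univariate_screen(cov, y))
        n_selected += sum(r.in_final_model for r in final)
    # 3 null factors x 10 replicates at a 0.1 screen: selections are rare
    assert n_selected <= 8


def test_or_rescaling_equivariance():
    """Scaling a covariate by c takes the per-unit OR to its c-th root."""
    rng = np.random.default_rng(9)
    x, y = _simulate_covariates(rng, 3000, beta=0.8)
    cov1 = pd.DataFrame({"x": x})
    cov10 = pd.DataFrame({"x": x * 10})
    r1 = stepwise_logistic(cov1, y, univariate_screen(cov1, y))[0]
    r10 = stepwise_logistic(cov10, y, univariate_screen(cov10, y))[0]
    assert r10.odds_ratio ** 10 == pytest.approx(r1.odds_ratio, rel=1e-4)
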
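"""Statistical layer: cohort comparisons and the noncompliance factor screen.

Cohort comparisons use a two-sample t test on mean PDC (pooled-variance
Student's t by default, Welch optional) and Pearson's chi-square on the 2x2
adherent/non-adherent split, without continuity correction. Multiplicity is
controlled by Bonferroni over the study's m = 6 prespecified tests
(significance iff p < 0.05/6 = 0.00833).

The factor screen models guideline noncompliance (fixed combination as
first-line therapy) as the outcome: each candidate factor gets a univariate
logistic regression on its complete cases; factors with likelihood-ratio
p < 0.1 enter a stepwise (forward entry / backward elimination, both at
p = 0.10) multivariate logistic model whose per-unit odds ratios and Wald
95% CIs are reported.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


class TTestVariant(str, enum.Enum):
    POOLED = "POOLED"
    WELCH = "WELCH"


@dataclass(frozen=True)
class StatsConfig:
    m_tests: int = 6
    alpha: float = 0.05
    univariate_entry_p: float = 0.1
    stepwise_entry_p: float = 0.10
    stepwise_stay_p: float = 0.10
    t_test_variant: TTestVariant = TTestVariant.POOLED
    chi_square_continuity_correction: bool = False

    def __post_init__(self) -> None:
        for name in ("alpha", "univariate_entry_p", "stepwise_entry_p", "stepwise_stay_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.m_tests < 1:
            raise ValueError("m_tests must be >= 1")

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / self.m_tests


def two_sample_t(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    variant: TTestVariant = TTestVariant.POOLED,
) -> tuple[float, float, float]:
    """Two-sample t test from summary statistics: (t, df, two-sided p)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant is TTestVariant.POOLED)
    )
    if variant is TTestVariant.POOLED:
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1 * sd1 / n1, sd2 * sd2 / n2
        df = (v1 + v2) ** 2 / (v1 * v1 / (n1 - 1) + v2 * v2 / (n2 - 1))
    return float(res.statistic), df, float(res.pvalue)


def chi_square_2x2(
    a: int, b: int, c: int, d: int, continuity_correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]]: (chi2, p).

    Continuity (Yates) correction is off by default, matching the plain
    Pearson statistic N(ad - bc)^2 / (row and column margin product).
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("cell counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("both margins must be positive")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=continuity_correction)
    return float(chi2), float(p)


def bonferroni_significant(p: float, config: StatsConfig = StatsConfig()) -> bool:
    """Significance under Bonferroni: strictly p < alpha / m."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    return p < config.bonferroni_threshold


@dataclass
class ScreenResult:
    factor: str
    univariate_p: float
    passed_screen: bool
    n_used: int
    separation_flag: bool = False
    in_final_model: bool = False
    odds_ratio: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    multivariate_p: float | None = None


def _design(covariates: pd.DataFrame, factors: Sequence[str]) -> pd.DataFrame:
    """Dummy-code categorical factors; numeric columns pass through."""
    cols = []
    for f in factors:
        col = covariates[f]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=f, drop_first=True, dtype=float)
            cols.append(dummies)
        else:
            cols.append(col.astype(float).to_frame(f))
    return pd.concat(cols, axis=1) if cols else pd.DataFrame(index=covariates.index)


def _logit_loglike(y: np.ndarray, X: np.ndarray) -> tuple[float, sm.Logit | None]:
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(disp=0, maxiter=200)
    return float(fit.llf), fit


def _lr_test(
    y: np.ndarray, X_full: np.ndarray, X_reduced: np.ndarray, df: int
) -> tuple[float, object]:
    ll_full, fit = _logit_loglike(y, X_full)
    ll_red, _ = _logit_loglike(y, X_reduced)
    lr = max(0.0, 2.0 * (ll_full - ll_red))
    return float(stats.chi2.sf(lr, df=df)), fit


def _is_separated(y: np.ndarray, design: pd.DataFrame) -> bool:
    # perfect or quasi-complete separation shows up as a one-column design
    # whose value ranges for y=0 and y=1 do not overlap
    for col in design.columns:
        x = design[col].to_numpy(dtype=float)
        x0, x1 = x[y == 0], x[y == 1]
        if len(x0) == 0 or len(x1) == 0:
            return True
        if x0.max() <= x1.min() or x1.max() <= x0.min():
            return True
    return False


def univariate_screen(
    covariates: pd.DataFrame,
    outcome: pd.Series,
    config: StatsConfig = StatsConfig(),
) -> list[ScreenResult]:
    """One single-factor logistic fit per covariate column, complete-case.

    Records the likelihood-ratio p-value against the intercept-only model
    and whether the factor passes the p < 0.1 screen. Factors showing
    separation are flagged and excluded (never silently dropped); a factor
    that is constant on its complete cases is likewise flagged.
    """
    y_all = outcome.astype(int)
    if y_all.nunique() < 2:
        raise ValueError("outcome must be non-constant binary")
    results: list[ScreenResult] = []
    for factor in covariates.columns:
        mask = covariates[factor].notna() & y_all.notna()
        sub = covariates.loc[mask, [factor]]
        y = y_all.loc[mask].to_numpy()
        n_used = int(mask.sum())
        if n_used == 0 or sub[factor].nunique() < 2 or len(np.unique(y)) < 2:
            results.append(
                ScreenResult(factor, np.nan, False, n_used, separation_flag=True)
            )
            continue
        design = _design(sub, [factor])
        if _is_separated(y, design):
            warnings.warn(f"factor {factor!r} shows separation; excluded from screen")
            results.append(
                ScreenResult(factor, np.nan, False, n_used, separation_flag=True)
            )
            continue
        X_full = sm.add_constant(design.to_numpy(dtype=float), has_constant="add")
        X_red = np.ones((n_used, 1))
        p, _ = _lr_test(y, X_full, X_red, df=design.shape[1])
        results.append(
            ScreenResult(factor, p, p < config.univariate_entry_p, n_used)
        )
    return results


def stepwise_logistic(
    covariates: pd.DataFrame,
    outcome: pd.Series,
    screened: Sequence[ScreenResult],
    config: StatsConfig = StatsConfig(),
) -> list[ScreenResult]:
    """Forward-entry / backward-elimination stepwise logistic regression.

    Candidates are the factors that passed the univariate screen. At each
    step the candidate with the smallest likelihood-ratio p enters if below
    the entry threshold; included factors whose removal p exceeds the stay
    threshold are dropped. The final model is fit on the complete cases of
    the selected factors; per-unit odds ratios carry Wald 95% CIs. An empty
    final model is a valid outcome.
    """
    candidates = [r.factor for r in screened if r.passed_screen]
    results = {r.factor: r for r in screened}
    selected: list[str] = []

    def with_const(design: pd.DataFrame, cols: list[str], n: int) -> np.ndarray:
        if not cols:
            return np.ones((n, 1))
        return sm.add_constant(design[cols].to_numpy(dtype=float), has_constant="add")

    def fit_on(factors: list[str]):
        mask = outcome.notna()
        for f in factors:
            mask &= covariates[f].notna()
        y = outcome.loc[mask].astype(int).to_numpy()
        design = _design(covariates.loc[mask], factors)
        return y, design

    changed = True
    while changed:
        changed = False
        # forward step
        best_p, best_f = None, None
        for f in [c for c in candidates if c not in selected]:
            y, design = fit_on(selected + [f])
            if len(np.unique(y)) < 2 or _is_separated(y, design[[
                c for c in design.columns if c == f or c.startswith(f + "_")
            ]]):
                continue
            X_full = sm.add_constant(design.to_numpy(dtype=float), has_constant="add")
            reduced_cols = [
                c for c in design.columns if not (c == f or c.startswith(f + "_"))
            ]
            X_red = with_const(design, reduced_cols, len(y))
            df = design.shape[1] - len(reduced_cols)
            p, _ = _lr_test(y, X_full, X_red, df=df)
            if best_p is None or p < best_p:
                best_p, best_f = p, f
        if best_f is not None and best_p < config.stepwise_entry_p:
            selected.append(best_f)
            changed = True
        # backward step
        worst_p, worst_f = None, None
        for f in selected:
            y, design = fit_on(selected)
            X_full = sm.add_constant(design.to_numpy(dtype=float), has_constant="add")
            reduced_cols = [
                c for c in design.columns if not (c == f or c.startswith(f + "_"))
            ]
            X_red = with_const(design, reduced_cols, len(y))
            df = design.shape[1] - len(reduced_cols)
            p, _ = _lr_test(y, X_full, X_red, df=df)
            if worst_p is None or p > worst_p:
                worst_p, worst_f = p, f
        if worst_f is not None and worst_p > config.stepwise_stay_p:
            selected.remove(worst_f)
            changed = True

    if not selected:
        return list(results.values())

    y, design = fit_on(selected)
    X = sm.add_constant(design.to_numpy(dtype=float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    z = stats.norm.ppf(0.975)
    for f in selected:
        # per-unit OR for the factor's (first) design column
        col_idx = next(
            i for i, c in enumerate(design.columns) if c == f or c.startswith(f + "_")
        )
        beta = fit.params[col_idx + 1]  # offset for the constant
        se = fit.bse[col_idx + 1]
        res = results[f]
        res.in_final_model = True
        res.odds_ratio = float(np.exp(beta))
        res.ci_low = float(np.exp(beta - z * se))
        res.ci_high = float(np.exp(beta + z * se))
        res.multivariate_p = float(fit.pvalues[col_idx + 1])
        res.n_used = len(y)
    return list(results.values())


def screen_to_frame(results: Sequence[ScreenResult]) -> pd.DataFrame:
    """Factor-screen table: factor, univariate p, final-model OR and CI."""
    return pd.DataFrame(
        {
            "factor": [r.factor for r in results],
            "n_used": [r.n_used for r in results],
            "univariate_p": [r.univariate_p for r in results],
            "passed_screen": [r.passed_screen for r in results],
            "separation_flag": [r.separation_flag for r in results],
            "in_final_model": [r.in_final_model for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "multivariate_p": [r.multivariate_p for r in results],
        }
    )
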
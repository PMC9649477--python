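"""Group-comparison statistics for the cohort tables.

Means are compared by Student or Welch t tests (from raw data or from
(n, mean, sd) summaries), non-normal variables by the Mann–Whitney U test,
and proportions by chi-square / Fisher exact tests. An age-adjusted
logistic regression tests the association between diagnosis and an
asymmetry index. All tests are two-sided. Because the assignment of
parametric vs non-parametric tests to individual variables is a modelling
choice, the comparison table reports all variants side by side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DegenerateROCError, DomainError


@dataclass
class GroupSummary:
    """(n, mean, sd) summary of one variable in one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise DomainError("need n >= 2 per group")
        if self.sd < 0:
            raise DomainError("sd must be non-negative")

    @classmethod
    def from_raw(cls, values) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        return cls(n=len(v), mean=float(v.mean()), sd=float(v.std(ddof=1)))


@dataclass
class TestReport:
    statistic: float
    p_value: float
    method: str
    degrees_of_freedom: float | None = None

    def __post_init__(self):
        if not (0 <= self.p_value <= 1 or np.isnan(self.p_value)):
            raise DomainError("p-value outside [0,1]")


def _as_summary(group) -> GroupSummary:
    return group if isinstance(group, GroupSummary) else GroupSummary.from_raw(group)


def two_sample_t(group_a, group_b, variant: str = "welch") -> TestReport:
    """Two-sided two-sample t test from raw values or summaries.

    `variant="student"` pools variances; `"welch"` (default) does not and
    uses Welch–Satterthwaite degrees of freedom.
    """
    if variant not in ("student", "welch"):
        raise DomainError(f"variant must be 'student' or 'welch', got {variant!r}")
    a, b = _as_summary(group_a), _as_summary(group_b)
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            return TestReport(0.0, 1.0, f"{variant}_t", float(a.n + b.n - 2))
        raise DataError("zero variance in both groups with unequal means")
    equal_var = variant == "student"
    t, p = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=equal_var
    )
    if equal_var:
        df = a.n + b.n - 2
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return TestReport(float(t), float(p), f"{variant}_t", float(df))


def mann_whitney(raw_a, raw_b) -> TestReport:
    """Two-sided Mann–Whitney U test.

    Exact null distribution for tie-free samples with combined n ≤ 20;
    tie-corrected normal approximation otherwise. Fully tied data give
    p = 1 by convention (no evidence of a shift).
    """
    a = np.asarray(raw_a, dtype=float)
    b = np.asarray(raw_b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise DataError("need at least one observation per group")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return TestReport(len(a) * len(b) / 2.0, 1.0, "mann_whitney")
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (tie_free and len(pooled) <= 20) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestReport(float(res.statistic), float(res.pvalue), "mann_whitney")


def proportion_test(count_a, n_a, count_b, n_b, method: str = "auto") -> TestReport:
    """Chi-square (or Fisher exact for sparse tables) test of two proportions."""
    table = np.array([[count_a, n_a - count_a], [count_b, n_b - count_b]])
    if np.any(table < 0):
        raise DomainError("counts out of range")
    expected = stats.contingency.expected_freq(table)
    if method == "fisher" or (method == "auto" and expected.min() < 5):
        odds, p = stats.fisher_exact(table)
        return TestReport(float(odds), float(p), "fisher_exact")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return TestReport(float(chi2), float(p), "chi_square", float(dof))


@dataclass
class LogisticReport:
    """Age-adjusted logistic fit of diagnosis on an asymmetry index."""

    params: pd.Series
    bse: pd.Series
    p_values: pd.Series
    converged: bool
    separation: bool          # fitted probabilities fully polarised / MLE absent
    quasi_separation: bool    # a fraction of observations perfectly predicted
    llf: float | None = None


def fit_logistic_adjusted(groups, ai_values, age, positive_label: str = "PD") -> LogisticReport:
    """Logistic regression of diagnosis on an AI, adjusted for age.

    Maximum-likelihood fit (IRLS/Newton) with Wald p-values. Complete or
    quasi-complete separation is detected and flagged instead of being
    reported as a converged estimate.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    groups = np.asarray(groups)
    y = (groups == positive_label).astype(float)
    if y.all() or not y.any():
        raise DegenerateROCError("both outcome classes must be present")
    X = pd.DataFrame({"ai": np.asarray(ai_values, float), "age": np.asarray(age, float)})
    if not np.all(np.isfinite(X.to_numpy())):
        raise DataError("predictors must be finite")
    Xc = sm.add_constant(X)

    separation = False
    quasi = False
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        try:
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        except Exception:
            # MLE does not exist (perfect separation): no finite estimate.
            nan = pd.Series(np.nan, index=Xc.columns)
            return LogisticReport(nan, nan, nan, converged=False,
                                  separation=True, quasi_separation=True)
    quasi = any(issubclass(w.category, PerfectSeparationWarning) for w in wlist)
    p_hat = fit.predict(Xc)
    if np.all(np.abs(p_hat - y) < 1e-4):
        separation = True
    return LogisticReport(
        params=fit.params, bse=fit.bse, p_values=fit.pvalues,
        converged=bool(fit.mle_retvals.get("converged", False)) and not separation,
        separation=separation, quasi_separation=quasi or separation, llf=float(fit.llf),
    )


def compare_groups(df: pd.DataFrame, group_col: str, continuous, categorical=(),
                   group_order=("PD", "CBS")) -> pd.DataFrame:
    """Two-group comparison table in means ± SD / n (%) form.

    For each continuous variable reports per-group mean±SD with Student t,
    Welch t and Mann–Whitney p-values; for each (binary) categorical
    variable, per-group counts with a chi-square/Fisher p-value.
    """
    g1, g2 = group_order
    d1, d2 = df[df[group_col] == g1], df[df[group_col] == g2]
    if len(d1) < 2 or len(d2) < 2:
        raise DataError("need at least two patients per group")
    rows = []
    for var in continuous:
        a, b = d1[var].to_numpy(float), d2[var].to_numpy(float)
        rows.append({
            "variable": var, "type": "continuous",
            f"{g1}_mean": a.mean(), f"{g1}_sd": a.std(ddof=1),
            f"{g2}_mean": b.mean(), f"{g2}_sd": b.std(ddof=1),
            "p_student_t": two_sample_t(a, b, "student").p_value,
            "p_welch_t": two_sample_t(a, b, "welch").p_value,
            "p_mann_whitney": mann_whitney(a, b).p_value,
        })
    for var, level in categorical:
        c1, c2 = int((d1[var] == level).sum()), int((d2[var] == level).sum())
        rep = proportion_test(c1, len(d1), c2, len(d2))
        rows.append({
            "variable": f"{var}={level}", "type": "categorical",
            f"{g1}_mean": c1, f"{g1}_sd": np.nan,
            f"{g2}_mean": c2, f"{g2}_sd": np.nan,
            "p_student_t": np.nan, "p_welch_t": np.nan,
            "p_mann_whitney": np.nan, "p_proportion": rep.p_value,
            "proportion_method": rep.method,
        })
    return pd.DataFrame(rows)
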
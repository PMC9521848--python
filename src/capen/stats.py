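"""Trial statistics: routed comparisons, effect sizes, chi-square,
regression screening, and paired-design power.

Conventions follow the source trial's analysis plan: normality is
checked per variable with Shapiro-Wilk at alpha = 0.05 and routes each
comparison to the parametric test (independent/paired t) or its rank
analogue (Mann-Whitney U / Wilcoxon signed-rank); all p-values are
two-tailed; the standardized mean difference pools the two SDs as the
root-mean of the variances, d = |m1 - m2| / sqrt((s1^2 + s2^2)/2) —
the only pooling convention that reproduces the trial's printed effect
sizes; no multiple-testing correction is applied across electrode
pairs by default (a Benjamini-Hochberg flag is available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "RegressionResult",
    "route_and_compare",
    "cohens_d_pooled",
    "chi_square",
    "screen_then_model",
    "paired_t_power",
    "two_sample_t_power",
]


@dataclass(frozen=True)
class ComparisonResult:
    """One two-group or paired comparison."""

    test_name: str
    statistic: float
    p_value: float
    n1: int
    n2: int
    effect_size: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass(frozen=True)
class RegressionResult:
    """OLS coefficients in the trial's reporting layout.

    ``table`` has one row per predictor with columns B (unstandardized
    coefficient), SE, b (standardized coefficient), t, p; ``r_squared``
    is the model R^2.
    """

    table: pd.DataFrame
    r_squared: float


def cohens_d_pooled(
    m1: float, s1: float, m2: float, s2: float, signed: bool = False
) -> float:
    """Standardized mean difference with root-mean-variance pooling.

    ``d = (m1 - m2) / sqrt((s1^2 + s2^2) / 2)``; reported as a
    magnitude by default to match the unsigned printed tables.
    """
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    denom = math.sqrt((s1 * s1 + s2 * s2) / 2.0)
    if denom == 0.0:
        raise ValueError("both SDs are zero: effect size undefined")
    d = (m1 - m2) / denom
    return d if signed else abs(d)


def _sample_d(a: np.ndarray, b: np.ndarray) -> float:
    s1 = float(a.std(ddof=1)) if len(a) > 1 else 0.0
    s2 = float(b.std(ddof=1)) if len(b) > 1 else 0.0
    if s1 == 0.0 and s2 == 0.0:
        return 0.0
    return cohens_d_pooled(float(a.mean()), s1, float(b.mean()), s2)


def _is_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    if np.ptp(x) == 0.0:  # constant: Shapiro undefined, treat as non-normal
        return False
    try:
        return sps.shapiro(x).pvalue >= alpha
    except ValueError:
        return False


def route_and_compare(
    sample_a, sample_b, paired: bool = False, normality_alpha: float = 0.05
) -> ComparisonResult:
    """Normality-routed two-group (or paired) comparison, two-tailed.

    Independent samples: Shapiro-Wilk on each sample; both normal ->
    independent t-test, otherwise Mann-Whitney U.  Paired samples:
    Shapiro-Wilk on the differences; normal -> paired t-test,
    otherwise Wilcoxon signed-rank (ties handled by the zero-split
    method when all differences vanish).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError(f"need n >= 3 per sample, got {len(a)} and {len(b)}")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired samples must have equal length")
        diff = a - b
        if np.all(diff == 0.0):
            return ComparisonResult("paired t-test", 0.0, 1.0, len(a), len(b), 0.0)
        if _is_normal(diff, normality_alpha):
            stat, p = sps.ttest_rel(a, b)
            name = "paired t-test"
        else:
            stat, p = sps.wilcoxon(a, b, zero_method="zsplit")
            name = "Wilcoxon signed-rank"
    else:
        if _is_normal(a, normality_alpha) and _is_normal(b, normality_alpha):
            stat, p = sps.ttest_ind(a, b)
            name = "independent t-test"
        else:
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
            name = "Mann-Whitney U"
    return ComparisonResult(
        name, float(stat), float(p), len(a), len(b), _sample_d(a, b)
    )


def chi_square(table) -> ComparisonResult:
    """Pearson chi-square on a 2 x k contingency table, no continuity correction."""
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be 2-dimensional with k >= 2 columns")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero row or column total: chi-square undefined")
    res = sps.chi2_contingency(t, correction=False)
    n1, n2 = (int(x) for x in t.sum(axis=1)[:2])
    # Cramer's V as the categorical effect size
    n = t.sum()
    k = min(t.shape) - 1
    v = math.sqrt(res.statistic / (n * k)) if k > 0 and n > 0 else 0.0
    return ComparisonResult(
        "Pearson chi-square", float(res.statistic), float(res.pvalue), n1, n2, v
    )


def _ols(y: np.ndarray, X: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    import statsmodels.api as sm

    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.values) < design.shape[1]:
        raise ValueError(
            "collinear predictor set: " + ", ".join(X.columns)
        )
    fit = sm.OLS(y, design).fit()
    sy = float(np.std(y, ddof=1))
    rows = []
    for name in X.columns:
        sx = float(X[name].std(ddof=1))
        rows.append(
            {
                "predictor": name,
                "B": fit.params[name],
                "SE": fit.bse[name],
                "b": fit.params[name] * sx / sy if sy > 0 else np.nan,
                "t": fit.tvalues[name],
                "p": fit.pvalues[name],
            }
        )
    return pd.DataFrame(rows).set_index("predictor"), float(fit.rsquared)


def screen_then_model(
    data: pd.DataFrame,
    outcome: str,
    candidates: list[str],
    group: str | None = None,
    screen_alpha: float = 0.2,
) -> tuple[RegressionResult, RegressionResult]:
    """Univariate OLS screening followed by a multivariate OLS model.

    Each candidate is regressed on the outcome alone; candidates with
    univariate p < ``screen_alpha`` (default 0.2), plus the ``group``
    term regardless of its univariate p, enter the multivariate model.
    Returns ``(univariate, multivariate)`` results; the univariate
    table carries one row per candidate (each from its own model) and
    an ``R2`` column with the per-model R^2.
    """
    y = np.asarray(data[outcome], dtype=float)
    cols = list(candidates)
    if group is not None and group not in cols:
        cols = [group] + cols
    uni_rows = []
    retained: list[str] = []
    for name in cols:
        if float(np.std(data[name])) == 0.0 and name != group:
            # constant candidate: nothing to estimate, never retained
            row = {
                "predictor": name, "B": 0.0, "SE": np.nan, "b": np.nan,
                "t": np.nan, "p": 1.0, "R2": 0.0,
            }
            uni_rows.append(row)
            continue
        tab, r2 = _ols(y, data[[name]])
        row = tab.loc[name].to_dict()
        row["predictor"] = name
        row["R2"] = r2
        uni_rows.append(row)
        if name == group or row["p"] < screen_alpha:
            retained.append(name)
    uni = pd.DataFrame(uni_rows).set_index("predictor")
    n_params = len(retained) + 1
    if len(data) <= n_params:
        raise ValueError(
            f"n={len(data)} too small for {len(retained)} retained predictors"
        )
    if not retained:  # nothing screened in: intercept-only model
        empty = pd.DataFrame(
            columns=["B", "SE", "b", "t", "p"], index=pd.Index([], name="predictor")
        )
        return RegressionResult(uni, float("nan")), RegressionResult(empty, 0.0)
    multi_tab, multi_r2 = _ols(y, data[retained])
    return (
        RegressionResult(uni, float("nan")),
        RegressionResult(multi_tab, multi_r2),
    )


def paired_t_power(
    dz: float, n: int, alpha: float = 0.05, alternative: str = "two-sided"
) -> float:
    """Achieved power of the paired t-test via the noncentral t.

    ``dz`` is the paired-design effect size (mean difference over SD of
    differences); df = n - 1, noncentrality dz * sqrt(n).  The trial's
    printed sample-size computation (dz = 1.0, n = 11, alpha = 0.05 ->
    0.924) corresponds to ``alternative="larger"`` (one-sided).
    """
    if dz < 0:
        raise ValueError("dz must be nonnegative")
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    df = n - 1
    ncp = dz * math.sqrt(n)
    if alternative == "two-sided":
        tc = sps.t.ppf(1.0 - alpha / 2.0, df)
        return float(1.0 - sps.nct.cdf(tc, df, ncp) + sps.nct.cdf(-tc, df, ncp))
    if alternative == "larger":
        tc = sps.t.ppf(1.0 - alpha, df)
        return float(1.0 - sps.nct.cdf(tc, df, ncp))
    raise ValueError(f"unknown alternative {alternative!r}")


def two_sample_t_power(
    d: float, n_per_group: int, alpha: float = 0.05
) -> float:
    """Two-tailed power of the two-sample t-test at effect size ``d``."""
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    df = 2 * n_per_group - 2
    ncp = d * math.sqrt(n_per_group / 2.0)
    tc = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(1.0 - sps.nct.cdf(tc, df, ncp) + sps.nct.cdf(-tc, df, ncp))


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (optional across-pair correction, off by default)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    ok = np.isfinite(p)
    out = np.full_like(p, np.nan)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
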
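"""Statistical primitives used throughout the analysis.

Pearson correlation with Fisher z confidence intervals, independent
two-sample t tests (with the companion F = t^2 often printed by SPSS-style
group comparisons), the chi-square test of independence, the pooled
two-proportion z test used for core-gene overlap comparisons, and
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ValidationError

#: two-sided 95% normal quantile as conventionally tabulated
Z_975 = 1.959964


@dataclass
class CorrelationResult:
    r: float
    n: int
    ci_low: float
    ci_high: float
    p: float
    p_adj: float | None = None
    label: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TestResult:
    statistic: float
    statistic_name: str  # "t", "F" or "chi2"
    df: float | tuple
    p: float
    f: float | None = None  # t^2 companion for two-group t tests

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d["df"], tuple):
            d["df"] = list(d["df"])
        return d


@dataclass
class OverlapZResult:
    k1: int
    n1: int
    k2: int
    n2: int
    p1: float
    p2: float
    z: float
    p: float

    def to_dict(self) -> dict:
        return asdict(self)


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher z-transform confidence interval for a Pearson correlation.

    z = atanh(r), half-width z_{alpha/2} / sqrt(n - 3), bounds tanh-back.
    Undefined at |r| = 1.
    """
    if not -1.0 < r < 1.0:
        raise ValidationError("fisher_ci requires |r| < 1")
    if n < 4:
        raise ValidationError("fisher_ci requires n >= 4")
    if not 0.0 < level < 1.0:
        raise ValidationError("confidence level must be in (0, 1)")
    crit = Z_975 if level == 0.95 else float(stats.norm.ppf(0.5 + level / 2.0))
    z = np.arctanh(r)
    half = crit / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def pearson_r(x, y, label: str | None = None) -> CorrelationResult:
    """Pearson correlation with t-based two-sided p and Fisher z CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson_r requires two equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise ValidationError("pearson_r requires n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("pearson_r input is constant")
    res = stats.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    if abs(r) < 1.0 and n >= 4:
        ci_low, ci_high = fisher_ci(r, n)
    else:
        ci_low = ci_high = r  # CI degenerate at |r| = 1 or tiny n
    return CorrelationResult(r=r, n=n, ci_low=ci_low, ci_high=ci_high, p=p, label=label)


def independent_t(a, b, equal_var: bool = False) -> TestResult:
    """Independent two-sample t test (Welch by default, pooled on request).

    Reports the companion F = t^2 with (1, df), matching the one-way-ANOVA
    presentation of a two-group comparison.  Two identical zero-variance
    groups return t = 0, p = 1 rather than NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("independent_t requires n >= 2 per group")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            df = float(a.size + b.size - 2)
            return TestResult(0.0, "t", df, 1.0, f=0.0)
        raise ValidationError("both groups constant with different means: t undefined")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    return TestResult(t, "t", df, p, f=t * t)


def chi_square_independence(table) -> TestResult:
    """Pearson chi-square test of independence on a 2 x k count table.

    No continuity correction (df = k - 1 for the 2 x k case).  Zero row or
    column margins are rejected.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != 2 or arr.shape[1] < 2:
        raise ValidationError("expected a 2 x k contingency table")
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValidationError("contingency table must hold nonnegative integers")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValidationError("contingency table has a zero row or column margin")
    res = stats.chi2_contingency(arr, correction=False)
    return TestResult(float(res.statistic), "chi2", float(res.dof), float(res.pvalue))


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> OverlapZResult:
    """Pooled-SE two-proportion z test, no continuity correction.

    z = |p1 - p2| / sqrt(phat (1 - phat) (1/n1 + 1/n2)) with
    phat = (k1 + k2) / (n1 + n2); two-sided normal p.  The absolute value is
    reported; the direction is carried by the proportions themselves.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1 or not 0 <= k <= n:
            raise ValidationError("counts must satisfy 0 <= k <= n, n >= 1")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise ValidationError("pooled proportion 0 or 1: standard error undefined")
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = abs(p1 - p2) / se
    p = float(2 * stats.norm.sf(z))
    return OverlapZResult(k1=k1, n1=n1, k2=k2, n2=n2, p1=p1, p2=p2,
                          z=float(z), p=min(p, 1.0))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order kept."""
    arr = np.asarray(pvals, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValidationError("bh_adjust expects a non-empty 1-D array")
    if np.any(arr < 0) or np.any(arr > 1) or not np.all(np.isfinite(arr)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]
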
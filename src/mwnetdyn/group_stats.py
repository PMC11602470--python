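"""Fixed two-group comparison procedure for dynamics metrics.

Per group: Tukey box-plot outlier removal (1.5 IQR beyond the quartiles,
linear-interpolation quartiles), then Shapiro-Wilk normality checks. Both
groups normal -> Levene's test decides between the pooled-variance and Welch
t-tests; otherwise the two-sided rank-sum test. Raw p-values, alpha = 0.05,
no multiplicity correction; the branch taken is recorded so every decision is
auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["ComparisonResult", "tukey_filter", "compare_groups"]


@dataclass
class ComparisonResult:
    metric: str
    n_a: int
    n_b: int
    test_used: str  # t-equal-var | t-unequal-var | rank-sum | insufficient
    statistic: float
    p_value: float
    significant: bool
    normal_a: bool | None = None
    normal_b: bool | None = None
    equal_var: bool | None = None


def tukey_filter(values) -> np.ndarray:
    """Drop values beyond 1.5 IQR outside the quartiles; <4 values pass through."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 4:
        warnings.warn("fewer than 4 values; outlier filter skipped", stacklevel=2)
        return v
    q1, q3 = np.percentile(v, [25, 75])  # linear interpolation
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return v[(v >= lo) & (v <= hi)]


def compare_groups(a, b, alpha: float = 0.05, metric: str = "") -> ComparisonResult:
    """Compare two samples with the fixed outlier/normality/variance cascade."""
    a = tukey_filter(a)
    b = tukey_filter(b)
    if a.size < 3 or b.size < 3:
        warnings.warn("insufficient sample size after outlier removal", stacklevel=2)
        return ComparisonResult(metric, a.size, b.size, "insufficient",
                                float("nan"), float("nan"), False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # Shapiro warns for tiny/tied samples
        norm_a = stats.shapiro(a).pvalue > 0.05 if a.std() > 0 else False
        norm_b = stats.shapiro(b).pvalue > 0.05 if b.std() > 0 else False
    equal_var = None
    if norm_a and norm_b:
        equal_var = stats.levene(a, b).pvalue > 0.05
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        test = "t-equal-var" if equal_var else "t-unequal-var"
    else:
        res = stats.ranksums(a, b)
        test = "rank-sum"
    p = float(res.pvalue)
    return ComparisonResult(
        metric=metric,
        n_a=int(a.size),
        n_b=int(b.size),
        test_used=test,
        statistic=float(res.statistic),
        p_value=p,
        significant=bool(p < alpha),
        normal_a=norm_a,
        normal_b=norm_b,
        equal_var=equal_var,
    )
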
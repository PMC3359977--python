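"""The four hypothesis tests used throughout the analyses.

Distributional comparisons of non-normal per-spot measures use the
two-sample Kolmogorov-Smirnov test or the Mann-Whitney U test; 2×2 spot
counts use the chi-square test with Yates' continuity correction; mean
comparisons use the two-tailed two-sample unequal-variance (Welch) t test.
All p values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

__all__ = [
    "TestResult",
    "ContingencyTable",
    "ks_test",
    "mwu_test",
    "chi_square_yates",
    "welch_t",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


@dataclass
class ContingencyTable:
    """2×2 table of counts [[a, b], [c, d]]."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table must hold at least one count")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def _clean(sample, name: str) -> np.ndarray:
    x = np.asarray(sample, dtype=float).ravel()
    if x.size == 0:
        raise ValueError(f"{name} is empty")
    return x


def ks_test(sample_a, sample_b, method: str = "asymp") -> TestResult:
    """Two-sample Kolmogorov-Smirnov test.

    The statistic is D = sup |ECDF_a − ECDF_b| and the p value uses the
    asymptotic Kolmogorov distribution by default (the variant calibrates
    well at the sample sizes used here); ``method="auto"`` or ``"exact"``
    switch to scipy's exact small-sample null distribution.
    """
    a, b = _clean(sample_a, "sample_a"), _clean(sample_b, "sample_b")
    res = _st.ks_2samp(a, b, method=method)
    return TestResult(float(res.statistic), float(res.pvalue), "ks_2samp", (a.size, b.size))


def mwu_test(sample_a, sample_b) -> TestResult:
    """Two-sided Mann-Whitney U test.

    The reported statistic is min(U_a, U_b), where U_a counts pairs won by
    sample a plus half the ties (so perfect separation yields 0 for the
    losing side and n_a·n_b for the winning side).  The p value is exact
    for n ≤ 8 per group without ties, and otherwise uses the tie-corrected
    normal approximation with continuity correction.
    """
    a, b = _clean(sample_a, "sample_a"), _clean(sample_b, "sample_b")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    small = max(a.size, b.size) <= 8
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = _st.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u_a = float(res.statistic)
    u_min = min(u_a, a.size * b.size - u_a)
    return TestResult(u_min, float(res.pvalue), "mann_whitney_u", (a.size, b.size))


def chi_square_yates(table) -> TestResult:
    """Chi-square test of a 2×2 table with Yates' continuity correction.

    χ² = N·(max(|ad − bc| − N/2, 0))² / ((a+b)(c+d)(a+c)(b+d)), df = 1,
    upper-tail p.  The correction is truncated at zero, so tables where it
    exceeds |ad − bc| give χ² = 0 and p = 1.
    """
    if isinstance(table, ContingencyTable):
        arr = table.as_array()
    else:
        arr = np.asarray(table, dtype=float)
        if arr.shape != (2, 2):
            raise ValueError("table must be 2×2")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
    (a, b), (c, d) = arr
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValueError("all row and column totals must be positive")
    num = max(abs(a * d - b * c) - n / 2.0, 0.0)
    chi2 = n * num**2 / margins
    p = float(_st.chi2.sf(chi2, df=1))
    return TestResult(float(chi2), p, "chi_square_yates", (int(a + b), int(c + d)))


def welch_t(sample_a, sample_b) -> TestResult:
    """Two-tailed two-sample unequal-variance (Welch) t test.

    Uses the Welch-Satterthwaite degrees of freedom.  Identical samples
    give t = 0; both samples must have at least two values and at least
    one must have positive variance.
    """
    a, b = _clean(sample_a, "sample_a"), _clean(sample_b, "sample_b")
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TestResult(0.0, 1.0, "welch_t", (a.size, b.size))
        raise ValueError("both samples are degenerate with unequal means")
    res = _st.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.pvalue), "welch_t", (a.size, b.size))
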
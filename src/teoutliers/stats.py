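"""Statistical primitives used across the pipeline.

All enrichment p-values come from the chi-square equality-of-proportions
test (the classic "prop test"), with the Yates continuity correction on by
default; the correction changes borderline p-values, so every report records
whether it was applied. Rank comparisons use the Wilcoxon rank-sum
(Mann-Whitney) test, exact for small samples and normal-approximated with
tie correction otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestReport:
    """Self-describing test result."""

    statistic: float
    p: float
    sides: str  # "one" or "two"
    method: str
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0 + 1e-12:
            raise ValueError(f"p-value {self.p} outside [0, 1]")


def _check_counts(x: int, n: int) -> None:
    if n < 1:
        raise ValueError("sample size must be >= 1")
    if not 0 <= x <= n:
        raise ValueError(f"count {x} outside [0, {n}]")


def prop_test(
    x1: int,
    n1: int,
    x2: int,
    n2: int,
    alternative: str = "two-sided",
    continuity: bool = True,
) -> TestReport:
    """Two-sample chi-square test of equal proportions.

    Mirrors the standard R-style computation on the 2x2 success/failure
    table, including the capped Yates correction, so borderline p-values are
    comparable with published ones.
    """
    _check_counts(x1, n1)
    _check_counts(x2, n2)
    x = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    n = np.array([n1, n2], dtype=float)
    p1, p2 = x1 / n1, x2 / n2
    delta = p1 - p2
    yates = 0.5 if continuity else 0.0
    yates = min(yates, abs(delta) / float(np.sum(1.0 / n)))
    expected = np.outer(x.sum(axis=1), x.sum(axis=0)) / x.sum()
    if (expected == 0).any():
        # all successes or all failures pooled: no evidence either way
        stat, p = 0.0, 1.0
    else:
        stat = float(np.sum((np.abs(x - expected) - yates) ** 2 / expected))
        p = float(sps.chi2.sf(stat, df=1))
    if alternative != "two-sided":
        z = np.sign(delta) * np.sqrt(stat)
        if alternative == "greater":
            p = float(sps.norm.sf(z))
        elif alternative == "less":
            p = float(sps.norm.cdf(z))
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    return TestReport(
        statistic=stat,
        p=min(p, 1.0),
        sides="two" if alternative == "two-sided" else "one",
        method="prop_test_2sample",
        details={
            "x1": x1,
            "n1": n1,
            "x2": x2,
            "n2": n2,
            "continuity": continuity,
            "estimate": (p1, p2),
        },
    )


def prop_test_1samp(
    x: int,
    n: int,
    p0: float,
    alternative: str = "two-sided",
    continuity: bool = True,
) -> TestReport:
    """One-sample chi-square test of a proportion against a fixed null p0."""
    _check_counts(x, n)
    if not 0.0 < p0 < 1.0:
        raise ValueError("null proportion must be strictly inside (0, 1)")
    expected = np.array([n * p0, n * (1.0 - p0)])
    observed = np.array([x, n - x], dtype=float)
    yates = 0.5 if continuity else 0.0
    yates = min(yates, abs(x - n * p0))
    stat = float(np.sum((np.abs(observed - expected) - yates) ** 2 / expected))
    p = float(sps.chi2.sf(stat, df=1))
    if alternative != "two-sided":
        z = np.sign(x / n - p0) * np.sqrt(stat)
        if alternative == "greater":
            p = float(sps.norm.sf(z))
        elif alternative == "less":
            p = float(sps.norm.cdf(z))
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    return TestReport(
        statistic=stat,
        p=min(p, 1.0),
        sides="two" if alternative == "two-sided" else "one",
        method="prop_test_1sample",
        details={"x": x, "n": n, "p0": p0, "continuity": continuity, "estimate": x / n},
    )


def wilcoxon_rank_sum(a, b, alternative: str = "two-sided") -> TestReport:
    """Wilcoxon rank-sum (Mann-Whitney U) test.

    Uses exact enumeration when both samples have <= 8 observations and no
    ties, otherwise the normal approximation with tie correction and
    continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = max(a.size, b.size) <= 8 and not has_ties
    res = sps.mannwhitneyu(
        a, b, alternative=alternative, method="exact" if exact else "asymptotic"
    )
    return TestReport(
        statistic=float(res.statistic),
        p=float(res.pvalue),
        sides="two" if alternative == "two-sided" else "one",
        method="wilcoxon_rank_sum_exact" if exact else "wilcoxon_rank_sum_normal",
        details={"n1": int(a.size), "n2": int(b.size)},
    )


def pearson_r(x, y) -> float:
    """Product-moment correlation; NaN when either vector has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(sps.pearsonr(x, y).statistic)


def proportion_se(p_hat: float, n: int) -> float:
    """Standard error of a sample proportion, sqrt(p(1-p)/n)."""
    if n < 1:
        raise ValueError("sample size must be >= 1")
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError("proportion outside [0, 1]")
    return float(np.sqrt(p_hat * (1.0 - p_hat) / n))
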
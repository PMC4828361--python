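"""Descriptive statistics and independent two-sample t-tests.

Group comparisons can be driven either by raw per-subject samples or by
printed summary statistics (mean, SD, n) — published tables report only the
latter, so the summary interface is what checks a printed comparison. The
default variant is the classic pooled-variance independent t-test; Welch's
unequal-variance form is available by flag. Two-sided p-values throughout;
no multiple-testing correction is applied (a caveat for table-wide scans).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np
from scipy import stats as sps

from .errors import StatsError

__all__ = [
    "GroupSummary",
    "TTestResult",
    "describe",
    "t_test_raw",
    "t_test_from_summary",
]

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    """Mean, sample SD (n-1 denominator) and count of one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise StatsError(f"group size must be >= 2, got n={self.n}")
        if self.sd < 0:
            raise StatsError("sd must be >= 0")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    alpha: float
    variant: str  # "pooled" | "welch"

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


def describe(samples) -> GroupSummary:
    """Mean and sample standard deviation of raw samples (n >= 2)."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise StatsError(f"describe needs >= 2 samples, got {x.size}")
    return GroupSummary(float(x.mean()), float(x.std(ddof=1)), int(x.size))


def t_test_from_summary(
    g1: GroupSummary,
    g2: GroupSummary,
    variant: str = "pooled",
    alpha: float = DEFAULT_ALPHA,
) -> TTestResult:
    """Independent two-sample t-test from (mean, sd, n) pairs.

    pooled:  sp^2 = ((n1-1) s1^2 + (n2-1) s2^2) / (n1+n2-2),
             t = (m1 - m2) / (sp sqrt(1/n1 + 1/n2)),  df = n1+n2-2
    welch:   t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2), Satterthwaite df
    """
    if variant not in ("pooled", "welch"):
        raise StatsError(f"unknown t-test variant {variant!r}")
    if not 0 < alpha < 1:
        raise StatsError("alpha must lie in (0, 1)")
    v1, v2 = g1.sd**2, g2.sd**2
    diff = g1.mean - g2.mean
    if v1 == 0 and v2 == 0:
        if diff == 0:
            raise StatsError("t undefined: zero variance in both groups, equal means")
        t = np.inf if diff > 0 else -np.inf
        df = float(g1.n + g2.n - 2)
        return TTestResult(float(t), df, 0.0, alpha, variant)
    if variant == "pooled":
        df = float(g1.n + g2.n - 2)
        sp2 = ((g1.n - 1) * v1 + (g2.n - 1) * v2) / df
        se = sqrt(sp2 * (1.0 / g1.n + 1.0 / g2.n))
    else:
        a, b = v1 / g1.n, v2 / g2.n
        se = sqrt(a + b)
        df = (a + b) ** 2 / (a**2 / (g1.n - 1) + b**2 / (g2.n - 1))
    t = diff / se
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TTestResult(float(t), float(df), p, alpha, variant)


def t_test_raw(
    a, b, variant: str = "pooled", alpha: float = DEFAULT_ALPHA
) -> TTestResult:
    """Independent two-sample t-test from raw samples (each group n >= 2)."""
    return t_test_from_summary(describe(a), describe(b), variant=variant, alpha=alpha)
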
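"""Shared two-sample statistics layer.

The nCounter engine compares final expression values with Welch's t-test;
the qPCR validation uses Student's t (equal variance) or Mann-Whitney U
depending on Shapiro-Wilk normality.  Both assays route through this module
so the variance assumption is a parameter rather than duplicated code.

One-sided p-values follow the usual convention: half the two-sided p when the
observed direction matches the hypothesised one, else one minus that half.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "welch_test",
    "student_test",
    "mann_whitney_test",
    "shapiro_normal",
    "welch_test_matrix",
]

Direction = Literal["up_in_b", "up_in_a", "none"]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample comparison of group A vs group B.

    ``statistic`` is t (t-family tests) or U (Mann-Whitney); positive t means
    group B's mean exceeds group A's.  ``df`` is NaN for Mann-Whitney.
    """

    statistic: float
    df: float
    p_two_sided: float
    p_one_sided: float
    direction: Direction
    test: str
    tied: bool = False


def _direction(mean_a: float, mean_b: float) -> Direction:
    if mean_b > mean_a:
        return "up_in_b"
    if mean_b < mean_a:
        return "up_in_a"
    return "none"


def _one_sided(p_two: float, observed: Direction, hypothesis: Optional[Direction]) -> float:
    if observed == "none":
        return min(1.0, p_two)  # no direction observed; one-sided is moot
    if hypothesis is None or hypothesis == observed:
        return p_two / 2.0
    return 1.0 - p_two / 2.0


def welch_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    hypothesis: Optional[Direction] = None,
) -> TestResult:
    """Welch's unequal-variance t-test of B vs A.

    t = (mean_b - mean_a) / sqrt(s_a^2/n_a + s_b^2/n_b) with
    Welch-Satterthwaite degrees of freedom.  Zero variance in both groups with
    equal means yields t = 0, p = 1 (a flat probe is simply not significant).
    """
    return _t_family(group_a, group_b, equal_var=False, hypothesis=hypothesis)


def student_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    hypothesis: Optional[Direction] = None,
) -> TestResult:
    """Unpaired Student's t-test (pooled variance) of B vs A."""
    return _t_family(group_a, group_b, equal_var=True, hypothesis=hypothesis)


def _t_family(group_a, group_b, equal_var: bool, hypothesis) -> TestResult:
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    direction = _direction(a.mean(), b.mean())
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return TestResult(0.0, float(a.size + b.size - 2), 1.0, 1.0, "none",
                              "student_t" if equal_var else "welch_t")
        # degenerate but directional: infinitely strong evidence
        t = np.inf if b.mean() > a.mean() else -np.inf
        return TestResult(
            float(t), float(a.size + b.size - 2), 0.0,
            _one_sided(0.0, direction, hypothesis), direction,
            "student_t" if equal_var else "welch_t",
        )
    if equal_var:
        n_a, n_b = a.size, b.size
        sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / (n_a + n_b - 2)
        t = (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / n_a + 1 / n_b))
        df = float(n_a + n_b - 2)
    else:
        se2_a, se2_b = va / a.size, vb / b.size
        t = (b.mean() - a.mean()) / np.sqrt(se2_a + se2_b)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (se2_a + se2_b) ** 2 / (
                se2_a**2 / (a.size - 1) + se2_b**2 / (b.size - 1)
            )
        if not np.isfinite(df):  # subnormal variances: squares underflow to 0
            df = float(a.size + b.size - 2)
    p_two = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult(
        float(t), float(df), p_two, _one_sided(p_two, direction, hypothesis),
        direction, "student_t" if equal_var else "welch_t",
    )


def mann_whitney_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    hypothesis: Optional[Direction] = None,
) -> TestResult:
    """Two-sided Mann-Whitney U of B vs A (exact when untied, else mid-rank
    normal approximation, flagged via ``tied``).

    Because the test ranks values, its p is invariant under any strictly
    increasing transform -- and flips direction but not p under decreasing
    transforms such as Cq -> 2^-Cq.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs at least 1 value")
    tied = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "asymptotic" if tied else "exact"
    res = sps.mannwhitneyu(b, a, alternative="two-sided", method=method)
    direction = _direction(float(np.median(a)), float(np.median(b)))
    if direction == "none":  # fall back to means for direction only
        direction = _direction(a.mean(), b.mean())
    p_two = float(res.pvalue)
    return TestResult(
        float(res.statistic), float("nan"), p_two,
        _one_sided(p_two, direction, hypothesis), direction, "mann_whitney",
        tied=tied,
    )


def shapiro_normal(values: Sequence[float], alpha: float = 0.05) -> tuple[float, bool]:
    """Shapiro-Wilk normality check; returns (p, passes).

    Constant samples have no distribution to speak of; they are reported as
    non-normal (p = 0) so callers route them to the rank test.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 values")
    if np.ptp(x) == 0.0:
        return 0.0, False
    p = float(sps.shapiro(x).pvalue)
    return p, p >= alpha


def welch_test_matrix(
    a: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised Welch test over rows: ``a`` (p x n_a) vs ``b`` (p x n_b).

    Returns (t, df, p_two_sided); rows with zero variance in both groups and
    equal means get t=0, p=1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2a, se2b = va / n_a, vb / n_b
    denom = np.sqrt(se2a + se2b)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mb - ma) / denom
        df = (se2a + se2b) ** 2 / (se2a**2 / (n_a - 1) + se2b**2 / (n_b - 1))
    flat = denom == 0.0
    equal_flat = flat & (ma == mb)
    t = np.where(equal_flat, 0.0, t)
    t = np.where(flat & ~equal_flat, np.where(mb > ma, np.inf, -np.inf), t)
    df = np.where(flat | ~np.isfinite(df), float(n_a + n_b - 2), df)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.where(equal_flat, 1.0, p)
    return t, df, p
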
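"""Self-contained statistical kernels shared by every analysis stage.

The workhorse is the Wilcoxon rank-sum (Mann-Whitney) test: exact by
enumeration for small samples, otherwise the normal approximation with tie
and continuity corrections.  The remaining kernels cover one-vs-rest auROC
marker scoring, multiple-testing adjustment, the Yates-corrected 2x2
chi-square used for intra/inter-chromosomal contingency, one-way ANOVA with
Tukey's HSD, standardized major axis (SMA) regression, and the permutation
Z-test used for TF-activity correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TestResult",
    "rank_sum_test",
    "auroc",
    "adjust_pvalues",
    "chi_square_2x2",
    "anova_tukey",
    "sma_fit",
    "perm_z_test",
]

#: largest min(n1, n2) for which the exact null distribution is enumerated
EXACT_MAX_MIN_N = 8


@dataclass
class TestResult:
    """Outcome of a hypothesis test.

    Attributes
    ----------
    statistic : float
        Test statistic (rank sum W, chi-square, F, or z depending on method).
    p : float
        P value in [0, 1].
    method : str
        Short identifier of the procedure that produced the result.
    sided : str
        ``two``, ``greater`` or ``less``.
    extra : dict
        Method-specific payload (e.g. Tukey pairwise table, degenerate flag).
    """

    statistic: float
    p: float
    method: str
    sided: str = "two"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p) or 0.0 <= self.p <= 1.0):
            raise ValueError(f"p value {self.p} outside [0, 1]")


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided p for the rank-sum of ``x`` by full enumeration.

    Enumerates every C(n1+n2, n1) assignment of the pooled (mid)ranks to the
    first sample, so ties are handled exactly.  p = 2 * min(P(W <= w),
    P(W >= w)), capped at 1.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    w_obs = float(ranks[:n1].sum())
    n_le = 0
    n_ge = 0
    total = 0
    eps = 1e-9
    for idx in combinations(range(len(pooled)), n1):
        w = float(ranks[list(idx)].sum())
        if w <= w_obs + eps:
            n_le += 1
        if w >= w_obs - eps:
            n_ge += 1
        total += 1
    p = 2.0 * min(n_le, n_ge) / total
    return w_obs, min(1.0, p)


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
) -> TestResult:
    """Two-sided Wilcoxon rank-sum test of ``x`` vs ``y``.

    ``mode='auto'`` enumerates the exact null distribution whenever
    ``min(n1, n2) <= 8`` and falls back to the normal approximation with tie
    and continuity corrections otherwise; ``'exact'`` and ``'normal'`` force
    a branch.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")

    use_exact = mode == "exact" or (
        mode == "auto" and min(x.size, y.size) <= EXACT_MAX_MIN_N
    )
    if use_exact:
        w, p = _exact_rank_sum_p(x, y)
        return TestResult(statistic=w, p=p, method="rank_sum_exact")

    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    ranks = stats.rankdata(np.concatenate([x, y]))
    w = float(ranks[: x.size].sum())
    return TestResult(statistic=w, p=float(res.pvalue), method="rank_sum_normal")


def auroc(x: Sequence[float], y: Sequence[float]) -> float:
    """Area under the ROC curve for separating ``x`` (positive) from ``y``.

    AUC = (#{x_i > y_j} + 0.5 #{x_i = y_j}) / (n_x * n_y), computed from the
    rank-sum identity so ties get half weight.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = ranks[: x.size].sum()
    u = r1 - x.size * (x.size + 1) / 2.0
    return float(u / (x.size * y.size))


# ---------------------------------------------------------------------------
# Multiple-testing adjustment
# ---------------------------------------------------------------------------

def adjust_pvalues(
    p: Sequence[float], method: str = "bonferroni", m: int | None = None
) -> np.ndarray:
    """Bonferroni or Benjamini-Hochberg adjustment of a p-value vector.

    ``m`` overrides the number of tests (useful when some tests were excluded
    upstream but still count toward the family).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    n = p.size
    if m is None:
        m = n
    if method == "bonferroni":
        return np.minimum(1.0, p * m)
    if method == "bh":
        order = np.argsort(p, kind="mergesort")
        ranked = p[order] * m / np.arange(1, n + 1)
        # step-up: enforce monotonicity from the largest p downward
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(n)
        out[order] = np.minimum(1.0, adj)
        return out
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# 2x2 contingency
# ---------------------------------------------------------------------------

def chi_square_2x2(table, yates: bool = True) -> TestResult:
    """Chi-square test of independence on a 2x2 table, Yates-corrected.

    chi2 = N (|ad - bc| - N/2)^2 / (r1 r2 c1 c2) with 1 df; the continuity
    correction never pushes the statistic below zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("table must be 2x2 nonnegative integers")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("all margins must be positive")
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2.0)
    chi2 = n * diff**2 / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(chi2, df=1))
    return TestResult(statistic=float(chi2), p=p, method="chi_square_yates" if yates else "chi_square")


# ---------------------------------------------------------------------------
# One-way ANOVA + Tukey HSD
# ---------------------------------------------------------------------------

def anova_tukey(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way ANOVA followed by Tukey's HSD pairwise comparisons.

    Returns the F test as the headline result; ``extra['tukey']`` maps each
    unordered pair of group indices to its HSD-adjusted p value from the
    studentized-range distribution.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    f, p = stats.f_oneway(*groups)
    if math.isnan(f):  # all values identical in every group
        f, p = 0.0, 1.0
    hsd = stats.tukey_hsd(*groups)
    pairwise = {
        (i, j): float(hsd.pvalue[i, j])
        for i in range(len(groups))
        for j in range(i + 1, len(groups))
    }
    return TestResult(
        statistic=float(f), p=float(p), method="anova_tukey", extra={"tukey": pairwise}
    )


# ---------------------------------------------------------------------------
# SMA regression
# ---------------------------------------------------------------------------

def sma_fit(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Standardized major axis regression: slope sign(r) * SD(y)/SD(x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired observations")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y")
    r = np.corrcoef(x, y)[0, 1]
    slope = math.copysign(sy / sx, r if r != 0 else 1.0)
    intercept = y.mean() - slope * x.mean()
    return float(slope), float(intercept)


# ---------------------------------------------------------------------------
# Permutation Z-test
# ---------------------------------------------------------------------------

def perm_z_test(observed: float, permuted_values: Sequence[float]) -> TestResult:
    """Z-test of an observed statistic against its permutation null.

    z = (observed - mean(perm)) / SD(perm), two-sided normal p.  A degenerate
    null (SD 0) yields p = 1 with ``extra['degenerate'] = True``.
    """
    perm = np.asarray(permuted_values, dtype=float)
    if perm.size < 2:
        raise ValueError("need at least 2 permuted values")
    sd = perm.std()  # population SD of the realized permutation null
    if sd == 0:
        return TestResult(
            statistic=float("nan"), p=1.0, method="perm_z", extra={"degenerate": True}
        )
    z = (observed - perm.mean()) / sd
    p = float(2.0 * stats.norm.sf(abs(z)))
    return TestResult(statistic=float(z), p=min(1.0, p), method="perm_z")
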
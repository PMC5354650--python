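"""Shared statistical kernels.

Every hypergeometric tail probability in the package (shared-miRNA test,
gene-set enrichment, mutated-hub enrichment) and every rank-sum test
(differential expression, mutated-degree comparison) goes through the two
functions here, so a single tested kernel backs all call sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["hypergeom_upper_tail", "rank_sum_test", "pearson_with_p", "RankSumResult"]


def hypergeom_upper_tail(M: int, K: int, n: int, x: int) -> float:
    """Upper-tail probability ``P(X >= x)`` for ``X ~ Hypergeometric(M, K, n)``.

    Parameters
    ----------
    M : population size.
    K : number of marked items in the population.
    n : number of items drawn without replacement.
    x : observed overlap.

    Raises ``ValueError`` when the bounds ``x <= min(K, n) <= M`` are violated.
    """
    M, K, n, x = int(M), int(K), int(n), int(x)
    if M < 0 or K < 0 or n < 0 or x < 0:
        raise ValueError("hypergeometric parameters must be non-negative")
    if K > M or n > M:
        raise ValueError(f"K={K} and n={n} must not exceed M={M}")
    if x > min(K, n):
        raise ValueError(f"overlap x={x} exceeds min(K, n)={min(K, n)}")
    if x == 0:
        return 1.0
    # sf(x-1) = P(X >= x); scipy's sf is a numerically stable tail sum.
    return float(stats.hypergeom.sf(x - 1, M, K, n))


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank-sum W of the first sample
    u: float  # Mann-Whitney U of the first sample
    pvalue: float
    method: str  # "exact" | "asymptotic" | "degenerate"


def rank_sum_test(
    x: np.ndarray,
    y: np.ndarray,
    alternative: str = "two-sided",
    exact_limit: int = 10,
) -> RankSumResult:
    """Wilcoxon rank-sum (Mann-Whitney) test of ``x`` versus ``y``.

    Exact enumeration of the null distribution is used when both samples
    have at most ``exact_limit`` observations and there are no ties; the
    tie-corrected normal approximation (no continuity correction) is used
    otherwise.  When every pooled value is identical the test is degenerate
    and ``p = 1`` is returned by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("samples must be one-dimensional")
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    n1 = x.size
    w_offset = n1 * (n1 + 1) / 2.0

    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        u = x.size * y.size / 2.0
        return RankSumResult(u + w_offset, u, 1.0, "degenerate")

    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and n1 <= exact_limit and y.size <= exact_limit:
        res = stats.mannwhitneyu(x, y, alternative=alternative, method="exact")
        return RankSumResult(float(res.statistic) + w_offset, float(res.statistic), float(res.pvalue), "exact")
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method="asymptotic", use_continuity=False
    )
    return RankSumResult(float(res.statistic) + w_offset, float(res.statistic), float(res.pvalue), "asymptotic")


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r and two-sided p from the t transform.

    ``t = r * sqrt((n-2) / (1-r^2))`` referred to a t distribution with
    ``n - 2`` degrees of freedom.  Requires length >= 3 and finite values;
    raises ``ValueError`` on zero variance (the caller decides how to skip).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance: correlation undefined")
    r = float((xc * yc).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, min(1.0, p)
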
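"""Replicate-level summary statistics and nonparametric comparisons.

Per-replicate grid-fit estimates are aggregated by median (for reporting
and between-line comparison) or mean (for fixing monoculture rates into
the competition equations).  Uncertainty on the median uses the exact
distribution-free binomial order-statistic interval; between-group
comparisons use the Wilcoxon rank-sum test with continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "aggregate_parameter",
    "MedianCI",
    "median_ci",
    "wilcoxon_rank_sum",
]


def aggregate_parameter(values, statistic: str = "median") -> float:
    """Median or mean of per-replicate parameter estimates."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one value")
    if statistic == "median":
        return float(np.median(arr))
    if statistic == "mean":
        return float(np.mean(arr))
    raise ValueError(f"unknown statistic {statistic!r}")


@dataclass(frozen=True)
class MedianCI:
    """Distribution-free confidence interval for the median.

    ``coverage`` is the achieved (conservative) confidence of the
    order-statistic pair actually used; ``conservative_flag`` is True
    when even the outermost pair cannot reach the requested level (small
    n) or the interval is otherwise degenerate.
    """

    median: float
    lower: float
    upper: float
    coverage: float
    conservative_flag: bool = False


def median_ci(values, level: float = 0.95) -> MedianCI:
    """Exact binomial order-statistic confidence interval for the median.

    For sorted values ``x_(1) <= ... <= x_(n)`` the interval
    ``[x_(k), x_(n+1-k)]`` covers the population median with probability
    ``1 - 2 P(Bin(n, 1/2) <= k - 1)``.  The innermost symmetric pair
    whose coverage reaches ``level`` is chosen; when no pair can (n too
    small), the outermost pair ``[x_(1), x_(n)]`` is returned with its
    achieved coverage and flagged conservative.

    With fewer than 3 values a degenerate min..max interval is returned,
    flagged.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    arr = np.sort(np.asarray(values, dtype=float))
    n = arr.size
    if n == 0:
        raise ValueError("need at least one value")
    med = float(np.median(arr))
    if n < 3:
        return MedianCI(med, float(arr[0]), float(arr[-1]),
                        coverage=float(1.0 - 2.0 * sps.binom.cdf(0, n, 0.5)) if n > 1 else 0.0,
                        conservative_flag=True)

    def cov(k: int) -> float:
        # coverage of [x_(k), x_(n+1-k)], 1-indexed
        return float(1.0 - 2.0 * sps.binom.cdf(k - 1, n, 0.5))

    best_k = None
    for k in range(n // 2, 0, -1):  # innermost to outermost
        if cov(k) >= level:
            best_k = k
            break
    if best_k is None:
        best_k = 1
        return MedianCI(med, float(arr[0]), float(arr[-1]), cov(1),
                        conservative_flag=True)
    return MedianCI(med, float(arr[best_k - 1]), float(arr[n - best_k]),
                    cov(best_k), conservative_flag=False)


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided permutation p for the rank-sum statistic.

    Enumerates all assignments of the pooled midranks to group x; ties are
    handled through midranks, so identical samples give p = 1.  Returns
    (W, p) with W the rank sum of x.
    """
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    nx = x.size
    w_obs = float(np.sum(ranks[:nx]))
    mu = ranks.sum() * nx / pooled.size
    d_obs = abs(w_obs - mu) - 1e-9  # tolerance for float midranks
    hits = 0
    total = 0
    for idx in combinations(range(pooled.size), nx):
        w = float(sum(ranks[i] for i in idx))
        if abs(w - mu) >= d_obs:
            hits += 1
        total += 1
    return w_obs, hits / total


def wilcoxon_rank_sum(x, y, continuity: bool = True) -> tuple[float, float]:
    """Wilcoxon rank-sum test, two-sided.

    Exact permutation enumeration (on midranks, so ties are handled) when
    the pooled sample has at most 12 observations; otherwise the normal
    approximation with tie-corrected variance and, if ``continuity``,
    continuity correction (via scipy's Mann-Whitney U).

    Returns
    -------
    (statistic, pvalue)
        ``statistic`` is the rank sum of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if x.size + y.size <= 12:
        return _exact_rank_sum_p(x, y)
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           use_continuity=continuity, method="asymptotic")
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0  # U -> rank sum
    return w, float(res.pvalue)
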
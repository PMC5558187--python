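"""Rank statistics and multiple-testing correction.

The Wilcoxon rank-sum test is implemented in-package because every
comparison in the pipeline runs through it and the exact small-sample
null distribution (including tied data) is needed with a fixed, documented
two-sided convention: the two-sided p-value is the total null probability
of rank sums at least as far from the null mean as the observed one, in
either tail — not a doubled one-sided tail.

Exact mode computes the permutation distribution of the rank sum by dynamic
programming over the observed mid-ranks (scaled by 2 so they are integers),
which is equivalent to enumerating all C(n1+n2, n1) assignments of the
observed value multiset.  The normal approximation applies the usual tie
correction to the variance and a 0.5 continuity correction.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import scipy.stats

__all__ = [
    "TestMode",
    "RankTestResult",
    "CorrectionResult",
    "SpearmanResult",
    "midranks",
    "wilcoxon_rank_sum",
    "bonferroni",
    "spearman_correlation",
]


class TestMode(str, enum.Enum):
    EXACT = "exact"
    NORMAL_APPROX = "normal_approx"


@dataclass(frozen=True)
class RankTestResult:
    statistic: float        # rank sum of the first sample (mid-ranks)
    n1: int
    n2: int
    p_two_sided: float
    mode: TestMode
    ties_present: bool

    def __post_init__(self) -> None:
        if not 0.0 < self.p_two_sided <= 1.0:
            raise ValueError(f"p-value out of range: {self.p_two_sided}")


@dataclass(frozen=True)
class CorrectionResult:
    raw_p: tuple
    adjusted_p: tuple
    family_size: int


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    degenerate: bool = False


def midranks(values: Sequence[float]) -> np.ndarray:
    """Mid-ranks (average ranks for ties), 1-based."""
    v = np.asarray(values, dtype=float)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v), dtype=float)
    sorted_v = v[order]
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


@lru_cache(maxsize=256)
def _ranksum_distribution(scaled_ranks: tuple, n1: int) -> tuple:
    """Null distribution of the (2x scaled) rank sum of a size-n1 subset.

    Returns (sums, counts): possible scaled rank sums over all C(N, n1)
    subsets of `scaled_ranks` with their multiplicities.  Dynamic programming
    over one rank at a time; counts are exact integers held in float64, which
    is lossless for N <= 60.
    """
    total = sum(scaled_ranks)
    # dp[k, s] = number of size-k subsets with scaled sum s
    dp = np.zeros((n1 + 1, total + 1))
    dp[0, 0] = 1.0
    for r in scaled_ranks:
        # iterate k downwards so each rank is used at most once
        for k in range(min(n1, 1 + int(np.nonzero(dp.any(axis=1))[0][-1])), 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    counts = dp[n1]
    sums = np.nonzero(counts)[0]
    return tuple(int(s) for s in sums), tuple(counts[sums])


def _exact_p(ranks: np.ndarray, n1: int, w: float) -> float:
    """Exact two-sided tail probability of rank sum `w` (first sample)."""
    scaled = tuple(int(round(2 * r)) for r in np.sort(ranks))
    n = len(scaled)
    sums, counts = _ranksum_distribution(scaled, n1)
    sums_arr = np.asarray(sums)
    counts_arr = np.asarray(counts)
    # null mean of the scaled rank sum is n1 * sum(scaled) / n; compare
    # distances after multiplying through by n to stay in exact integers
    total = sum(scaled)
    w2 = int(round(2 * w))
    observed_dist = abs(n * w2 - n1 * total)
    dists = np.abs(n * sums_arr - n1 * total)
    tail = counts_arr[dists >= observed_dist].sum()
    return float(tail / counts_arr.sum())


def _approx_p(ranks: np.ndarray, n1: int, n2: int, w: float) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations identical
        return 1.0
    diff = abs(w - mu)
    z = max(diff - 0.5, 0.0) / math.sqrt(var)
    return min(1.0, math.erfc(z / math.sqrt(2.0)))


# exact enumeration is kept to modest sizes; beyond this the normal
# approximation is indistinguishable at any tolerance this pipeline uses
_EXACT_LIMIT = 20


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum test of samples `x` and `y`.

    `mode` is "auto" (exact when n1+n2 <= 20, else normal approximation),
    "exact", or "approx".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    n1, n2 = len(x), len(y)
    ranks = midranks(np.concatenate([x, y]))
    ties = len(np.unique(ranks)) < n1 + n2
    w = float(ranks[:n1].sum())

    if mode == "auto":
        use_exact = n1 + n2 <= _EXACT_LIMIT
    elif mode == "exact":
        use_exact = True
    elif mode == "approx":
        use_exact = False
    else:
        raise ValueError(f"mode must be auto|exact|approx, got {mode!r}")

    if use_exact:
        p = _exact_p(ranks, n1, w)
        result_mode = TestMode.EXACT
    else:
        p = _approx_p(ranks, n1, n2, w)
        result_mode = TestMode.NORMAL_APPROX
    return RankTestResult(w, n1, n2, max(p, np.finfo(float).tiny), result_mode, ties)


def bonferroni(
    raw_p: Sequence[float], family_size: Optional[int] = None
) -> CorrectionResult:
    """Bonferroni correction: adjusted p = min(1, family_size * raw p)."""
    raw = tuple(float(p) for p in raw_p)
    for p in raw:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p-values must lie in (0, 1], got {p}")
    m = len(raw) if family_size is None else int(family_size)
    if m < len(raw):
        raise ValueError(
            f"family_size ({m}) smaller than the number of tests ({len(raw)})"
        )
    adjusted = tuple(min(1.0, m * p) for p in raw)
    return CorrectionResult(raw, adjusted, m)


def spearman_correlation(
    x: Sequence[float], y: Sequence[float]
) -> SpearmanResult:
    """Spearman rank correlation with mid-ranks for ties and a t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("samples must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rx, ry = midranks(x), midranks(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        return SpearmanResult(math.nan, math.nan, n, degenerate=True)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * scipy.stats.t.sf(abs(t), df=n - 2))
    return SpearmanResult(rho, p, n)
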
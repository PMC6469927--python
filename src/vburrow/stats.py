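"""Inferential tests used in burrow-assay analyses, from first principles.

The central test is the pooled two-proportion z-test on trial counts, used
one-tailed with the null hypothesis that the probability of ingress in the
tested condition is less than or equal to that in the reference condition.
The canonical form — pooled variance, no continuity correction, upper-tail
normal p — is adopted because it is the unique combination that makes the
test's p-values recomputable from raw ingress counts.

Also provided: the Wilcoxon rank-sum test (average ranks for ties,
tie-corrected normal approximation, exact enumeration for small samples)
and an upper-tail normal kernel accurate to ~1e-15 relative error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "TwoProportionResult",
    "RankSumResult",
    "two_proportion_z",
    "wilcoxon_rank_sum",
    "normal_sf",
]


def normal_sf(z: float) -> float:
    """Upper-tail standard normal probability 1 - Phi(z)."""
    if not math.isfinite(z):
        raise ValueError("z must be finite")
    return 0.5 * math.erfc(z / math.sqrt(2.0))


@dataclass(frozen=True)
class TwoProportionResult:
    z: float
    p: float
    k1: int
    n1: int
    k2: int
    n2: int
    alternative: str

    @property
    def proportions(self) -> tuple[float, float]:
        return self.k1 / self.n1, self.k2 / self.n2


def two_proportion_z(k1: int, n1: int, k2: int, n2: int,
                     alternative: str = "greater") -> TwoProportionResult:
    """Pooled two-proportion z-test on success counts.

    ``alternative='greater'`` tests H1: p1 > p2 (upper-tail p of z);
    ``'two-sided'`` doubles the smaller tail.  No continuity correction.

    Raises if the pooled proportion is degenerate (all successes or all
    failures), where the statistic is undefined.
    """
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or not 0 <= k <= n:
            raise ValueError("need 0 <= k <= n with n > 0")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled <= 0.0 or pooled >= 1.0:
        raise ValueError("pooled proportion is degenerate; test undefined")
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (k1 / n1 - k2 / n2) / se
    if alternative == "greater":
        p = normal_sf(z)
    else:
        p = min(1.0, 2.0 * normal_sf(abs(z)))
    return TwoProportionResult(z=z, p=p, k1=k1, n1=n1, k2=k2, n2=n2,
                               alternative=alternative)


@dataclass(frozen=True)
class RankSumResult:
    statistic: float   # rank sum of the first sample
    p: float
    method: str        # "exact" or "normal"
    alternative: str
    degenerate: bool   # all pooled values identical


def _ranksum_normal_p(w: float, n1: int, n2: int, pooled: np.ndarray,
                      alternative: str) -> float:
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie = float((counts.astype(np.float64) ** 3 - counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var <= 0:
        return 1.0
    d = w - mu
    # continuity correction toward the mean
    d = math.copysign(max(abs(d) - 0.5, 0.0), d) if d != 0 else 0.0
    z = d / math.sqrt(var)
    if alternative == "greater":
        return normal_sf(z)
    if alternative == "less":
        return normal_sf(-z)
    return min(1.0, 2.0 * normal_sf(abs(z)))


def _ranksum_exact_p(w: float, n1: int, ranks: np.ndarray,
                     alternative: str) -> float:
    """Full enumeration of the rank-sum distribution over assignments."""
    n = len(ranks)
    ws = np.array([ranks[list(c)].sum()
                   for c in combinations(range(n), n1)])
    eps = 1e-9
    lo = float(np.mean(ws <= w + eps))
    hi = float(np.mean(ws >= w - eps))
    if alternative == "greater":
        return hi
    if alternative == "less":
        return lo
    return min(1.0, 2.0 * min(lo, hi))


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided",
                      exact_max_n: int = 12) -> RankSumResult:
    """Wilcoxon rank-sum test with average ranks for ties.

    The statistic is the sum of the ranks of ``x`` in the pooled sample.
    For combined sample size at most ``exact_max_n`` the p-value comes from
    full enumeration of rank assignments; otherwise from the tie-corrected
    normal approximation with continuity correction.

    If every pooled value is identical the test is degenerate; p = 1 by
    convention, flagged in the result.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError("bad alternative")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[:x.size].sum())
    if np.all(pooled == pooled[0]):
        return RankSumResult(statistic=w, p=1.0, method="degenerate",
                             alternative=alternative, degenerate=True)
    if x.size + y.size <= exact_max_n:
        p = _ranksum_exact_p(w, x.size, ranks, alternative)
        method = "exact"
    else:
        p = _ranksum_normal_p(w, x.size, y.size, pooled, alternative)
        method = "normal"
    return RankSumResult(statistic=w, p=p, method=method,
                         alternative=alternative, degenerate=False)
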
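"""Nonparametric group comparisons.

Two-sample comparisons use the two-sided Wilcoxon rank-sum test.  For small
groups (both below 10 observations) the p-value is exact, computed from the
full permutation distribution of the rank sum by a subset-sum dynamic
program over doubled midranks (doubling makes tied midranks integral); for
larger groups a normal approximation with the usual tie-corrected variance
is used.  The two-sided exact p-value is the probability, under the null, of
a rank sum at least as far from its expectation as the observed one.

Three-group latency comparisons use the Kruskal-Wallis H test with pairwise
rank-sum post-hocs under Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, erf, sqrt
from typing import Optional, Sequence

import numpy as np
from scipy.stats import kruskal, rankdata


class StatsError(ValueError):
    pass


@dataclass
class GroupComparison:
    metric: str
    group_labels: tuple
    group_sizes: tuple
    test: str
    statistic: float
    p_value: float
    posthoc: Optional[dict] = None


def _exact_ranksum_p(ranks2: np.ndarray, n_a: int, w2_obs: float) -> float:
    """Exact two-sided p for the rank sum of group A.

    ranks2 are the pooled midranks times two (integers); the DP counts, for
    every achievable doubled rank sum s of an n_a-subset, the number of
    subsets attaining it.
    """
    ranks2 = np.asarray(np.round(ranks2), dtype=int)
    total_sum = int(ranks2.sum())
    n = ranks2.size
    dp = np.zeros((n_a + 1, total_sum + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        for k in range(n_a, 0, -1):  # descending so each item is used once
            dp[k, r:] += dp[k - 1, : total_sum + 1 - r]
    counts = dp[n_a]
    total = comb(n, n_a)
    mu2 = n_a * (n + 1)  # doubled expectation n_a*(n+1)/2 * 2
    dev = abs(w2_obs - mu2)
    sums = np.arange(total_sum + 1)
    extreme = np.abs(sums - mu2) >= dev - 1e-9
    return float(counts[extreme].sum() / total)


def _normal_ranksum_p(ranks: np.ndarray, n_a: int, w_obs: float) -> float:
    """Tie-corrected normal approximation, no continuity correction."""
    n = ranks.size
    n_b = n - n_a
    mu = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / ((n) * (n - 1.0))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (w_obs - mu) / sqrt(var)
    return float(2.0 * (1.0 - 0.5 * (1.0 + erf(abs(z) / sqrt(2.0)))))


def rank_sum_test(values_a: Sequence[float], values_b: Sequence[float]):
    """Two-sided Wilcoxon rank-sum test; returns (W_a, p).

    Exact when both groups have fewer than 10 observations, normal
    approximation with tie correction otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsError("rank-sum test requires two nonempty groups")
    if np.any(~np.isfinite(a)) or np.any(~np.isfinite(b)):
        raise StatsError("rank-sum test requires finite values")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    w = float(ranks[: a.size].sum())
    if a.size < 10 and b.size < 10:
        p = _exact_ranksum_p(2.0 * ranks, a.size, 2.0 * w)
    else:
        p = _normal_ranksum_p(ranks, a.size, w)
    return w, min(p, 1.0)


def compare_groups(values_a, values_b, metric: str = "",
                   labels: tuple = ("a", "b")) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum comparison of two cell populations."""
    w, p = rank_sum_test(values_a, values_b)
    return GroupComparison(
        metric=metric, group_labels=tuple(labels),
        group_sizes=(len(values_a), len(values_b)),
        test="wilcoxon_ranksum", statistic=w, p_value=p)


def compare_latency_groups(direct, indirect_a, indirect_b,
                           metric: str = "latency_ms",
                           labels: tuple = ("direct", "indirect_a", "indirect_b"),
                           ) -> GroupComparison:
    """Kruskal-Wallis H across three latency groups plus Bonferroni-corrected
    pairwise rank-sum post-hocs."""
    groups = [np.asarray(g, dtype=float) for g in (direct, indirect_a, indirect_b)]
    if any(g.size == 0 for g in groups):
        raise StatsError("Kruskal-Wallis requires three nonempty groups")
    if all(np.all(g == groups[0][0]) for g in groups):
        h, p = 0.0, 1.0  # scipy rejects all-identical input
    else:
        h, p = kruskal(*groups)
    posthoc = {}
    pairs = [(0, 1), (0, 2), (1, 2)]
    for i, j in pairs:
        _, p_pair = rank_sum_test(groups[i], groups[j])
        posthoc[f"{labels[i]}_vs_{labels[j]}"] = min(1.0, p_pair * len(pairs))
    return GroupComparison(
        metric=metric, group_labels=tuple(labels),
        group_sizes=tuple(g.size for g in groups),
        test="kruskal_wallis", statistic=float(h), p_value=float(p),
        posthoc=posthoc)
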
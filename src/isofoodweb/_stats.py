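"""Nonparametric test machinery shared by the baseline screens and the
equation-comparison report.

All tests operate on mid-ranks. The two-sample test delegates to
:func:`scipy.stats.mannwhitneyu` (exact null enumeration for small tie-free
samples, normal approximation with tie correction otherwise); Kruskal–Wallis
delegates to :func:`scipy.stats.kruskal`. Dunn's pairwise post hoc z-tests are
implemented here on pooled mid-ranks with tie correction, because they operate
on the same rank pool as the omnibus test rather than on per-pair re-rankings.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

EXACT_MAX_N = 8  # exact rank-sum enumeration up to this group size (no ties)


@dataclass(frozen=True)
class PairwiseResult:
    """One Dunn pairwise comparison on pooled mid-ranks."""

    group_a: str
    group_b: str
    z: float
    p_raw: float
    p_adjusted: float
    significant: bool


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test.

    Uses exact enumeration of the null when both groups have at most
    ``EXACT_MAX_N`` observations and the pooled sample is tie-free; otherwise
    the normal approximation with tie correction (no continuity correction, so
    exchangeable samples give p = 1).

    Returns
    -------
    (statistic, p_value) : the U statistic for ``x`` and the two-sided p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError(
            f"rank-sum test needs >= 2 observations per group, got {x.size} and {y.size}"
        )
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # every observation identical: no evidence against exchangeability
        return float(x.size * y.size / 2.0), 1.0
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


def _tie_term(pooled_ranks_source: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of the pooled sample."""
    _, counts = np.unique(pooled_ranks_source, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) and its chi-square p-value."""
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2:
        raise ValueError("Kruskal-Wallis needs >= 2 groups")
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def dunn_posthoc(
    groups: dict[str, np.ndarray],
    alpha_level: float = 0.05,
    p_adjust: str = "bonferroni",
) -> list[PairwiseResult]:
    """Dunn's pairwise z-tests on pooled mid-ranks with tie correction.

    For groups i, j with mean pooled ranks Ri, Rj out of N observations:

        z = (Ri - Rj) / sqrt((N(N+1)/12 - T/(12(N-1))) * (1/ni + 1/nj))

    where T = sum(t^3 - t) over tie groups. Two-sided p-values, optionally
    Bonferroni-adjusted across all unordered pairs.
    """
    labels = list(groups)
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    pooled = np.concatenate([arrays[k] for k in labels])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks: dict[str, float] = {}
    sizes: dict[str, int] = {}
    start = 0
    for k in labels:
        n = arrays[k].size
        mean_ranks[k] = float(np.mean(ranks[start : start + n]))
        sizes[k] = n
        start += n

    tie_corr = _tie_term(pooled) / (12.0 * (n_total - 1))
    variance_base = n_total * (n_total + 1) / 12.0 - tie_corr

    pairs = list(itertools.combinations(labels, 2))
    m = len(pairs)
    results = []
    for a, b in pairs:
        se = np.sqrt(variance_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p_raw = float(2.0 * stats.norm.sf(abs(z)))
        if p_adjust == "bonferroni":
            p_adj = min(1.0, p_raw * m)
        elif p_adjust in (None, "none"):
            p_adj = p_raw
        else:
            raise ValueError(f"unknown p_adjust {p_adjust!r}")
        results.append(
            PairwiseResult(a, b, float(z), p_raw, p_adj, p_adj < alpha_level)
        )
    return results


def friedman_test(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Paired (repeated-measures) alternative to the omnibus comparison.

    Treats each index across groups as one subject measured under every
    variant. All groups must have equal length.
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    lengths = {a.size for a in arrays}
    if len(lengths) != 1:
        raise ValueError("Friedman test requires equal group sizes (paired design)")
    stat, p = stats.friedmanchisquare(*arrays)
    return float(stat), float(p)
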
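"""Nonparametric group statistics and the binomial selection-frequency
significance criterion.

Two conventions are exposed for inverting the binomial tail when deciding
how often a feature must be selected to beat chance:

``exact_tail``
    the literal inversion -- smallest k with exact P(X >= k) <= alpha;
    at (n=100, p=1/3, alpha=0.05) this gives 42.

``paper_compat``
    one count stricter than the literal inversion (critical count =
    exact_tail + 1); at (n=100, p=1/3, alpha=0.05) this gives the widely
    quoted threshold of 43.  Use this for replication-style reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "BinomialThresholdSpec",
    "binomial_critical_count",
    "flag_significant_features",
    "kruskal_wallis",
    "dunn_sidak_pairwise",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
]


@dataclass(frozen=True)
class BinomialThresholdSpec:
    n: int = 100
    p: float = 1.0 / 3.0
    alpha: float = 0.05
    convention: str = "paper_compat"

    def __post_init__(self) -> None:
        if not 0 < self.p < 1:
            raise ValueError("p must lie in (0, 1)")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @property
    def critical_k(self) -> int:
        return binomial_critical_count(self.n, self.p, self.alpha, self.convention)


def binomial_critical_count(
    n: int, p: float, alpha: float, convention: str = "exact_tail"
) -> int:
    """Smallest selection count deemed significant under Binomial(n, p).

    ``exact_tail``: smallest k with P(X >= k) <= alpha (exact upper-tail
    sum).  ``paper_compat``: exact_tail + 1, capped at n.  alpha = 1 is the
    vacuous threshold 0 under both conventions.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    # sf(k-1) = P(X >= k) is non-increasing in k; scan for the first hit.
    k = next(
        kk for kk in range(n + 2) if sps.binom.sf(kk - 1, n, p) <= alpha
    )
    if convention == "exact_tail":
        return k
    if convention == "paper_compat":
        # k = n + 1 means no count qualifies; keep that sentinel as-is
        return 0 if k == 0 else min(k + 1, n + 1)
    raise ValueError(f"unknown convention {convention!r}")


def flag_significant_features(
    counts: np.ndarray,
    n: int = 100,
    p: float = 1.0 / 3.0,
    alpha: float = 0.05,
    convention: str = "paper_compat",
) -> np.ndarray:
    """Boolean flags: count >= critical_k (boundary inclusive)."""
    counts = np.asarray(counts)
    if np.any(counts < 0) or np.any(counts > n):
        raise ValueError("counts must lie in [0, n]")
    critical = binomial_critical_count(n, p, alpha, convention)
    return counts >= critical


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Rank-based H test with tie correction; chi-square p on len-1 df.

    All-identical observations return (0, 1) rather than erroring.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    res = sps.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


def dunn_sidak_pairwise(
    groups: list[np.ndarray],
) -> list[tuple[int, int, float, float]]:
    """Dunn's pairwise z tests on pooled ranks with Sidak adjustment.

    Returns (i, j, z, p_adjusted) per unordered pair; the raw two-sided
    normal p is adjusted as 1 - (1 - p)^m for m pairs, clipped to [0, 1].
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    pooled = np.concatenate(arrays)
    ranks = sps.rankdata(pooled)
    big_n = pooled.size
    sizes = [a.size for a in arrays]
    mean_ranks = []
    start = 0
    for size in sizes:
        mean_ranks.append(ranks[start : start + size].mean())
        start += size
    # tie correction for the rank variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    variance_base = big_n * (big_n + 1) / 12.0
    if big_n > 1:
        variance_base -= tie_term / (12.0 * (big_n - 1))
    m = len(arrays) * (len(arrays) - 1) // 2
    out = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            se = np.sqrt(variance_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            p_raw = 2.0 * sps.norm.sf(abs(z))
            p_adj = float(np.clip(1.0 - (1.0 - min(p_raw, 1.0)) ** m, 0.0, 1.0))
            out.append((i, j, float(z), p_adj))
    return out


def wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum test: exact distribution for combined n <= 25
    with no ties, normal approximation with tie/continuity correction
    otherwise.  Returns (rank-sum of x, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= 25 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0
    p = float(res.pvalue)
    if has_ties and np.all(pooled == pooled[0]):
        p = 1.0
    return w, min(p, 1.0)


def wilcoxon_signed_rank(x: np.ndarray, mu: float = 0.0) -> tuple[float, float]:
    """Two-sided signed-rank test of symmetry about ``mu``; zero
    differences are dropped, and all-zero differences give p = 1."""
    d = np.asarray(x, dtype=float) - mu
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0
    method = "exact" if d.size <= 25 and np.unique(np.abs(d)).size == d.size else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", method=method, correction=True)
    return float(res.statistic), float(res.pvalue)
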
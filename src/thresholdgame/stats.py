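"""Exact small-sample nonparametric tests for group-level comparisons.

With only ten groups per treatment, asymptotic rank tests are on shaky
ground, so the signed-rank and rank-sum tests here compute *exact*
two-sided p-values by complete enumeration of the null distribution over
the observed mid-rank tie structure (a dynamic program over subset/sign
rank sums; ties get mid-ranks and the enumeration respects them).  The
two-sided convention is the doubled one-sided exact tail, capped at 1.

Fisher's exact test uses the probability-mass rule (sum of hypergeometric
probabilities no larger than the observed table's), and the k-sample tests
(Kruskal-Wallis, Friedman) report chi-square-approximate p-values with
mid-rank tie correction, optionally accompanied by a seeded Monte-Carlo
permutation p-value.

Statistic conventions match common reporting practice: signed-rank reports
the sum of positive ranks; the rank-sum statistic is the larger of U and
U' (so ten groups per sample put it on the 0..100 scale).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "fisher_exact_2x2",
    "signed_rank_test",
    "rank_sum_test",
    "kruskal_wallis",
    "friedman",
]

_EXACT_LIMIT_SIGNED = 25  # enumerate 2^n sign assignments up to here
_EXACT_LIMIT_RANKSUM = 12  # per-sample size limit for exact enumeration


@dataclass(frozen=True)
class TestResult:
    """Outcome of one group-level hypothesis test."""

    method: str
    statistic: float
    p_value: float
    sidedness: str = "two_sided"
    exact: bool = True
    n_per_sample: tuple[int, ...] = ()
    permutation_p: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p-value out of range: {self.p_value}")


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher exact test by the probability-mass rule.

    The p-value sums the probabilities of all 2x2 tables with the observed
    margins whose hypergeometric probability does not exceed that of the
    observed table.  Degenerate margins give p = 1 by convention.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)) or (arr < 0).any():
            raise ValueError("counts must be nonnegative integers")
        arr = arr.astype(int)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return TestResult("fisher_exact", 1.0, 1.0, n_per_sample=tuple(arr.sum(axis=1)))
    odds, p = sps.fisher_exact(arr, alternative="two-sided")
    return TestResult(
        "fisher_exact", float(odds), float(min(p, 1.0)), n_per_sample=tuple(arr.sum(axis=1))
    )


def _doubled_int_ranks(ranks: np.ndarray) -> np.ndarray:
    """Mid-ranks doubled to integers (mid-ranks are multiples of 1/2)."""
    doubled = np.round(ranks * 2).astype(int)
    if not np.allclose(doubled / 2.0, ranks):
        raise ValueError("ranks are not half-integers")
    return doubled


def _signed_rank_null_counts(doubled: np.ndarray) -> np.ndarray:
    """counts[s] = number of sign assignments with positive-rank sum s/2."""
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=object)
    counts[0] = 1
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def signed_rank_test(values: Sequence[float], reference: float = 0.0) -> TestResult:
    """Exact Wilcoxon signed-rank test of a sample against a reference value.

    Zeros are dropped, tied absolute differences get mid-ranks, and the
    statistic is the sum of positive ranks.  For n <= 25 the two-sided
    p-value is the doubled exact tail over all 2^n sign assignments
    (computed by dynamic programming); larger n fall back to the normal
    approximation.
    """
    d = np.asarray(values, dtype=float) - reference
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult("signed_rank", 0.0, 1.0, n_per_sample=(0,))
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= _EXACT_LIMIT_SIGNED:
        doubled = _doubled_int_ranks(ranks)
        counts = _signed_rank_null_counts(doubled)
        denom = 2**n
        w2 = int(round(w_plus * 2))
        lower = int(sum(counts[: w2 + 1]))
        upper = int(sum(counts[w2:]))
        p = min(1.0, 2.0 * min(lower, upper) / denom)
        return TestResult("signed_rank", w_plus, p, exact=True, n_per_sample=(n,))
    res = sps.wilcoxon(d, alternative="two-sided", correction=True)
    return TestResult("signed_rank", w_plus, float(res.pvalue), exact=False, n_per_sample=(n,))


def _ranksum_null_counts(doubled: np.ndarray, n1: int) -> np.ndarray:
    """counts[s] = number of size-n1 subsets of the rank multiset with sum s/2."""
    total = int(doubled.sum())
    counts = np.zeros((n1 + 1, total + 1), dtype=object)
    counts[0, 0] = 1
    for r in doubled:
        nxt = counts.copy()
        nxt[1:, r:] = nxt[1:, r:] + counts[:-1, : total + 1 - r]
        counts = nxt
    return counts[n1]


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Exact Mann-Whitney / Wilcoxon rank-sum test for two independent samples.

    The statistic is the larger of U and U' (range 0..n1*n2).  For samples
    of at most 12 each, the two-sided p-value is the doubled exact tail of
    the permutation distribution of the rank sum over the observed tie
    structure; larger samples use the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u_stat = max(u1, n1 * n2 - u1)
    if max(n1, n2) <= _EXACT_LIMIT_RANKSUM:
        doubled = _doubled_int_ranks(ranks)
        counts = _ranksum_null_counts(doubled, n1)
        from math import comb

        denom = comb(n1 + n2, n1)
        r2 = int(round(r1 * 2))
        lower = int(sum(counts[: r2 + 1]))
        upper = int(sum(counts[r2:]))
        p = min(1.0, 2.0 * min(lower, upper) / denom)
        return TestResult("rank_sum", u_stat, p, exact=True, n_per_sample=(n1, n2))
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult("rank_sum", u_stat, float(res.pvalue), exact=False, n_per_sample=(n1, n2))


def _permutation_p_kruskal(
    samples: list[np.ndarray], observed: float, rng: np.random.Generator, n_perm: int
) -> float:
    pooled = np.concatenate(samples)
    sizes = [len(s) for s in samples]
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        parts = np.split(pooled, np.cumsum(sizes)[:-1])
        try:
            h = sps.kruskal(*parts).statistic
        except ValueError:  # all identical after shuffle
            h = 0.0
        if h >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def kruskal_wallis(
    samples: Sequence[Sequence[float]],
    n_permutations: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> TestResult:
    """Kruskal-Wallis H test with chi-square p and optional permutation p."""
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if len(arrays) < 2:
        raise ValueError("need at least two samples")
    sizes = tuple(len(a) for a in arrays)
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult("kruskal_wallis", 0.0, 1.0, exact=False, n_per_sample=sizes)
    res = sps.kruskal(*arrays)
    perm_p = None
    if n_permutations > 0:
        perm_p = _permutation_p_kruskal(
            arrays, float(res.statistic), np.random.default_rng(rng), n_permutations
        )
    return TestResult(
        "kruskal_wallis",
        float(res.statistic),
        float(res.pvalue),
        exact=False,
        n_per_sample=sizes,
        permutation_p=perm_p,
    )


def friedman(
    block_matrix: Sequence[Sequence[float]],
    n_permutations: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> TestResult:
    """Friedman test on a blocks x conditions matrix (groups x rounds).

    Mid-ranks within blocks with tie correction; chi-square p-value with
    conditions - 1 degrees of freedom, optionally a seeded permutation p
    (independently permuting conditions within each block).
    """
    m = np.asarray(block_matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("block_matrix must be 2-D with at least two conditions")
    n_blocks, k = m.shape

    def _stat(mat: np.ndarray) -> float:
        ranks = np.apply_along_axis(sps.rankdata, 1, mat)
        col_sums = ranks.sum(axis=0)
        chisq = 12.0 / (n_blocks * k * (k + 1)) * np.sum(col_sums**2) - 3 * n_blocks * (k + 1)
        # tie correction within blocks
        correction = 0.0
        for row in mat:
            _, counts = np.unique(row, return_counts=True)
            correction += float(np.sum(counts**3 - counts))
        c = 1.0 - correction / (n_blocks * k * (k**2 - 1))
        return chisq / c if c > 0 else 0.0

    statistic = _stat(m)
    if statistic <= 0:
        return TestResult("friedman", 0.0, 1.0, exact=False, n_per_sample=(n_blocks, k))
    p = float(sps.chi2.sf(statistic, k - 1))
    perm_p = None
    if n_permutations > 0:
        gen = np.random.default_rng(rng)
        hits = 0
        for _ in range(n_permutations):
            shuffled = np.array([gen.permutation(row) for row in m])
            if _stat(shuffled) >= statistic - 1e-12:
                hits += 1
        perm_p = (hits + 1) / (n_permutations + 1)
    return TestResult(
        "friedman", float(statistic), min(p, 1.0) if p > 0 else np.nextafter(0, 1),
        exact=False, n_per_sample=(n_blocks, k), permutation_p=perm_p,
    )
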
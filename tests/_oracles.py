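"""Independent brute-force oracles used to check the exact rank tests."""

from itertools import combinations, product

import numpy as np
from scipy import stats as sps


def brute_force_signed_rank_p(d: np.ndarray) -> tuple[float, float]:
    """Statistic and two-sided p by enumerating all 2^n sign assignments."""
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    lower = upper = 0
    for signs in product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        lower += w <= w_obs + 1e-9
        upper += w >= w_obs - 1e-9
    denom = 2**n
    return w_obs, min(1.0, 2.0 * min(lower, upper) / denom)


def brute_force_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided p by enumerating all C(n1+n2, n1) rank assignments."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    r_obs = ranks[:n1].sum()
    lower = upper = total = 0
    for idx in combinations(range(len(pooled)), n1):
        r = ranks[list(idx)].sum()
        lower += r <= r_obs + 1e-9
        upper += r >= r_obs - 1e-9
        total += 1
    return min(1.0, 2.0 * min(lower, upper) / total)
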
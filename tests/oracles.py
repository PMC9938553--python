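"""Independent statistical oracles used by the acceptance-level tests.

These never call the code paths they check: the Mann-Whitney null
distribution comes from the classic counting recurrence, type-I rates are
exact expectations over enumerated null distributions, and AUC is brute
pair counting.
"""

import numpy as np
from scipy import stats


def mann_whitney_null_pmf(m: int, n: int) -> np.ndarray:
    """Exact null pmf of the Mann-Whitney U statistic for tie-free samples
    of sizes (m, n), via the counting recurrence
    f(m, n, u) = f(m-1, n, u-n) + f(m, n-1, u)."""
    grid = {}
    for j in range(n + 1):
        grid[(0, j)] = np.array([1.0])
    for i in range(1, m + 1):
        grid[(i, 0)] = np.array([1.0])
        for j in range(1, n + 1):
            a = grid[(i - 1, j)]
            b = grid[(i, j - 1)]
            size = i * j + 1
            out = np.zeros(size)
            out[j : j + a.size] += a
            out[: b.size] += b
            grid[(i, j)] = out
    pmf = grid[(m, n)]
    return pmf / pmf.sum()


def samples_with_u(u: int, m: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Construct tie-free samples (x of size m, y of size n) whose
    Mann-Whitney U statistic (pairs with x > y) equals ``u`` exactly."""
    assert 0 <= u <= m * n
    # greedy digits: x_i sits above exactly c_i of the y's
    cs = [min(n, max(0, u - n * i)) for i in range(m)]
    y = np.array([100.0 * (j + 1) for j in range(n)])
    x = np.array([100.0 * c + 1.0 + 0.001 * i for i, c in enumerate(cs)])
    return x, y


def exact_ranksum_type1(p_of_xy, m: int = 30, n: int = 30, alpha: float = 0.05) -> float:
    """Exact type-I rate of a rank-sum p-value function for continuous null
    data: the p-value depends on the data only through U, so evaluate it at
    every achievable U and weight by the exact null pmf."""
    pmf = mann_whitney_null_pmf(m, n)
    rate = 0.0
    for u in range(m * n + 1):
        if pmf[u] == 0:
            continue
        x, y = samples_with_u(u, m, n)
        if p_of_xy(x, y) < alpha:
            rate += pmf[u]
    return float(rate)


def exact_fisher_type1(p_of_table, n_row: int = 100, p: float = 0.5,
                       alpha: float = 0.05, tol: float = 1e-10) -> float:
    """Exact type-I rate of a 2x2 test under independent Binomial(n_row, p)
    rows, by enumerating the (non-negligible) joint table distribution."""
    pmf = stats.binom.pmf(np.arange(n_row + 1), n_row, p)
    keep = np.flatnonzero(pmf > tol)
    rate = 0.0
    for a in keep:
        wa = pmf[a]
        for c in keep:
            if p_of_table(int(a), n_row - int(a), int(c), n_row - int(c)) < alpha:
                rate += wa * pmf[c]
    return float(rate)


def exact_cp_coverage(ci_of_k, p: float, n: int) -> float:
    """Exact coverage of a binomial CI procedure at true proportion p:
    sum the binomial pmf over the outcomes whose interval covers p."""
    cover = 0.0
    for k in range(n + 1):
        lo, hi = ci_of_k(k, n)
        if lo <= p <= hi:
            cover += stats.binom.pmf(k, n, p)
    return float(cover)


def auc_pair_count(scores, labels) -> float:
    """Brute-force AUC: correctly ranked (diseased, control) pairs with ties
    at half credit — the Mann-Whitney identity."""
    s, y = np.asarray(scores, float), np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    wins = 0.0
    for a in pos:
        wins += np.sum(a > neg) + 0.5 * np.sum(a == neg)
    return float(wins / (len(pos) * len(neg)))
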
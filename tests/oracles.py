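"""Brute-force enumeration oracles, independent of the package's scipy path.

All functions work from ``math.comb`` alone so they can adjudicate the
package's exact-test implementations. Two-sided p-values use the
minimum-likelihood convention: sum the probabilities of all outcomes no
more likely than the observed one. A tiny relative slack guards the
inclusion comparison against floating-point ties.
"""

import math

_REL_SLACK = 1e-9


def binom_pmf(k: int, n: int, p: float) -> float:
    return math.comb(n, k) * p**k * (1 - p) ** (n - k)


def binom_p_two_sided(k: int, n: int, p: float) -> float:
    observed = binom_pmf(k, n, p)
    total = sum(
        pm
        for j in range(n + 1)
        if (pm := binom_pmf(j, n, p)) <= observed * (1 + _REL_SLACK)
    )
    return min(1.0, total)


def binom_p_greater(k: int, n: int, p: float) -> float:
    return min(1.0, sum(binom_pmf(j, n, p) for j in range(k, n + 1)))


def fisher_p_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Hypergeometric enumeration over all tables with the observed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = [math.comb(r1, x) * math.comb(r2, c1 - x) / denom for x in range(lo, hi + 1)]
    observed = probs[a - lo]
    return min(1.0, sum(p for p in probs if p <= observed * (1 + _REL_SLACK)))


def mannwhitney_p_exact(x, y) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration of rank assignments."""
    from itertools import combinations

    pooled = sorted(x) + sorted(y)
    n_x = len(x)
    all_idx = range(len(pooled))

    def u_stat(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in all_idx if i not in set(idx)]
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    u_obs = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
    n_total = 0
    n_extreme = 0
    mid = len(x) * len(y) / 2
    for idx in combinations(all_idx, n_x):
        u = u_stat(idx)
        n_total += 1
        if abs(u - mid) >= abs(u_obs - mid) - 1e-12:
            n_extreme += 1
    return n_extreme / n_total
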
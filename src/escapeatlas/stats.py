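"""Exact-test kernels shared across the pipeline.

Two-sided exact binomial p-values use the minimum-likelihood convention:
the p-value sums the probabilities of all outcomes whose point probability
does not exceed that of the observed count. This is the convention used by
``scipy.stats.binomtest`` and by base R's ``binom.test``; it is stated
explicitly here because exact-test implementations differ.

Fisher's exact test reports the two-sided p together with two odds-ratio
estimators: the cross-product (sample) estimator a·d/(b·c) with a Woolf
logit 95% CI, and the conditional maximum-likelihood estimator, because
published implementations differ on which one they print.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def binom_pvalue_two_sided(k: int, n: int, p: float) -> float:
    """Exact two-sided binomial p-value (minimum-likelihood method)."""
    if n == 0:
        return 1.0
    return float(sps.binomtest(int(k), int(n), float(p)).pvalue)


def binom_pvalue_greater(k: int, n: int, p: float) -> float:
    """Exact one-sided binomial p-value, P(X >= k)."""
    if n == 0:
        return 1.0
    return float(
        sps.binomtest(int(k), int(n), float(p), alternative="greater").pvalue
    )


@dataclass(frozen=True)
class FisherResult:
    """2x2 enrichment result with both odds-ratio estimators."""

    table: Tuple[Tuple[int, int], Tuple[int, int]]
    odds_ratio: float  # sample (cross-product) estimator
    odds_ratio_cmle: float  # conditional MLE
    ci95: Tuple[float, float]  # Woolf logit interval on the sample estimator
    p_value: float
    sidedness: str = "two-sided"


def fisher_exact_2x2(a: int, b: int, c: int, d: int, cmle: bool = True) -> FisherResult:
    """Two-sided Fisher exact test on [[a, b], [c, d]].

    A zero row or column margin makes the test degenerate: p = 1 and the
    odds ratio is undefined (NaN). ``cmle=False`` skips the (iterative)
    conditional-MLE odds ratio when only the p-value is needed.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("table counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("table total must be > 0")
    table = ((int(a), int(b)), (int(c), int(d)))
    degenerate = (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0)
    if degenerate:
        return FisherResult(table, math.nan, math.nan, (math.nan, math.nan), 1.0)

    if b * c == 0:
        sample_or = math.inf if a * d > 0 else math.nan
    else:
        sample_or = (a * d) / (b * c)
    if min(a, b, c, d) > 0:
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        log_or = math.log(sample_or)
        ci = (math.exp(log_or - 1.959963984540054 * se),
              math.exp(log_or + 1.959963984540054 * se))
    else:
        ci = (math.nan, math.nan)
    cmle_or = (
        float(sps.contingency.odds_ratio(np.asarray(table)).statistic)
        if cmle
        else math.nan
    )
    p = float(sps.fisher_exact(np.asarray(table), alternative="two-sided")[1])
    return FisherResult(table, sample_or, cmle_or, ci, p)


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted q-values (NaNs pass through)."""
    p = np.asarray(list(pvalues), dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def dunn_test(groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None):
    """Dunn's post hoc test after Kruskal–Wallis, with BH correction.

    Pairwise z statistics compare mean ranks on the pooled ranking, with the
    standard tie correction; two-sided normal p-values are BH-adjusted.
    Returns a list of dicts (group_a, group_b, z, p, p_adj).
    """
    import pandas as pd

    k = len(groups)
    if labels is None:
        labels = [str(i) for i in range(k)]
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = pooled.size
    ranks = sps.rankdata(pooled)
    sizes = [len(g) for g in groups]
    mean_ranks = []
    start = 0
    for s in sizes:
        mean_ranks.append(ranks[start : start + s].mean())
        start += s
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1)) if n > 1 else 0.0
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = math.sqrt(
                (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j])
            )
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else math.nan
            p = 2 * sps.norm.sf(abs(z)) if not math.isnan(z) else math.nan
            rows.append({"group_a": labels[i], "group_b": labels[j], "z": z, "p": p})
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"])
    return df
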
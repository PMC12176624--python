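"""Positional analyses along the X chromosome.

Gene position means the annotation start coordinate throughout, so
clusters, window assignment and distances all use a single consistent
point per gene. Escape clusters are single-linkage chains: consecutive
sorted positions closer than the maximum gap belong to one cluster, so a
cluster's span can exceed the gap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .stats import bh_adjust, binom_pvalue_two_sided


@dataclass(frozen=True)
class EscapeCluster:
    member_positions: Tuple[int, ...]
    span: Tuple[int, int]

    @property
    def size(self) -> int:
        return len(self.member_positions)


def cluster_escapees(positions: Sequence[int], max_gap: int) -> List[EscapeCluster]:
    """Single-linkage clustering of positions on one chromosome.

    Positions are sorted and chained; a break occurs whenever the gap to
    the next position exceeds ``max_gap``. Singletons are valid clusters.
    """
    pos = sorted(int(p) for p in positions)
    if not pos:
        return []
    clusters: List[List[int]] = [[pos[0]]]
    for p in pos[1:]:
        if p - clusters[-1][-1] > max_gap:
            clusters.append([p])
        else:
            clusters[-1].append(p)
    return [
        EscapeCluster(tuple(c), (c[0], c[-1])) for c in clusters
    ]


def nearest_distance(
    query: Sequence[int], reference: Sequence[int], threshold: int
) -> Tuple[np.ndarray, float]:
    """Minimum absolute distance from each query position to the reference set.

    Returns (distances, fraction of queries within ``threshold``).
    """
    ref = np.sort(np.asarray(list(reference), dtype=float))
    if ref.size == 0:
        raise ValueError("reference position set is empty")
    q = np.asarray(list(query), dtype=float)
    idx = np.searchsorted(ref, q)
    left = np.abs(q - ref[np.clip(idx - 1, 0, ref.size - 1)])
    right = np.abs(ref[np.clip(idx, 0, ref.size - 1)] - q)
    dist = np.minimum(left, right)
    frac = float(np.mean(dist <= threshold)) if q.size else float("nan")
    return dist, frac


def sliding_window_enrichment(
    positions: Sequence[int],
    aged_flags: Sequence[bool],
    window: int,
    step: int,
    chrom_length: int,
    global_fraction: Optional[float] = None,
    chrom: str = "chrX",
) -> pd.DataFrame:
    """Aged-escapee enrichment in sliding windows along the chromosome.

    Per window [start, start+window), enrichment = escapees identified in
    aged / total escapees located there, tested with an exact two-sided
    binomial against ``global_fraction`` (default: the chromosome-wide
    aged fraction of the input). Empty windows report NaN enrichment and
    p = 1. BH q-values are co-emitted.
    """
    pos = np.asarray(list(positions), dtype=np.int64)
    aged = np.asarray(list(aged_flags), dtype=bool)
    if pos.size != aged.size:
        raise ValueError("positions and aged_flags must align")
    if global_fraction is None:
        global_fraction = float(aged.mean()) if pos.size else 0.5
        if global_fraction in (0.0, 1.0):
            # no contrast: every escapee is (or none are) aged-identified,
            # so each window trivially matches the chromosome-wide fraction
            degenerate = True
        else:
            degenerate = False
    elif not 0.0 < global_fraction < 1.0:
        raise ValueError("global_fraction must lie strictly in (0, 1)")
    else:
        degenerate = False
    rows = []
    start = 0
    while start < chrom_length:
        end = min(start + window, chrom_length)
        in_win = (pos >= start) & (pos < start + window)
        total = int(in_win.sum())
        n_aged = int((in_win & aged).sum())
        if total == 0:
            enrich, p = np.nan, 1.0
        else:
            enrich = n_aged / total
            p = (
                1.0
                if degenerate
                else binom_pvalue_two_sided(n_aged, total, global_fraction)
            )
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "count_aged": n_aged,
                "count_total": total,
                "enrichment": enrich,
                "p_value": p,
            }
        )
        start += step
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"])
    return out


@dataclass(frozen=True)
class DistalResult:
    n: int
    n_distal: int
    fraction: float
    null_probability: float
    p_value: float


def distal_fraction(
    positions: Sequence[int], chrom_length: int, head: int, tail: int
) -> DistalResult:
    """Fraction of positions in the distal chromosome regions, with binomial test.

    Distal means pos < ``head`` or pos >= ``chrom_length`` − ``tail``. The
    exact two-sided binomial null probability is (head + tail) /
    chrom_length (uniform placement).
    """
    if head + tail >= chrom_length:
        raise ValueError("head + tail must be < chrom_length")
    pos = np.asarray(list(positions), dtype=np.int64)
    if pos.size == 0:
        return DistalResult(0, 0, float("nan"), (head + tail) / chrom_length, 1.0)
    distal = (pos < head) | (pos >= chrom_length - tail)
    n_distal = int(distal.sum())
    p0 = (head + tail) / chrom_length
    p = binom_pvalue_two_sided(n_distal, pos.size, p0)
    return DistalResult(int(pos.size), n_distal, n_distal / pos.size, p0, p)


def clusters_to_bed(clusters: Sequence[EscapeCluster], chrom: str = "chrX") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": [c.span[0] for c in clusters],
            "end": [c.span[1] + 1 for c in clusters],
            "n_members": [c.size for c in clusters],
        }
    )
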
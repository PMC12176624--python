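"""Allele-specific chromatin accessibility (ATAC) analyses.

Peak identity across samples comes from a union annotation: peaks called
in any timepoint or replicate are merged wherever they overlap by at
least 1 bp. Window assignment uses the peak midpoint so every peak lands
in exactly one window. The aged-enrichment null assumes equal peak
numbers between timepoints (binomial p = 0.5, one-sided).
"""

from __future__ import annotations

import math
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .allelic import compute_ar
from .config import AnalysisConfig
from .io import RegulatoryElement
from .stats import FisherResult, binom_pvalue_greater, fisher_exact_2x2

ESCAPE_PEAK = "escape_peak"
XA_SPECIFIC = "xa_specific"
NOT_INFORMATIVE = "not_informative"

DYN_DE_NOVO = "de_novo_aged"
DYN_SWITCH = "switch_to_biallelic"
DYN_STABLE = "stable"


def merge_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    """Union-merge called peaks (chrom, start, end) into one annotation.

    Overlap of >= 1 bp (half-open intervals) joins peaks; the result gets
    stable ``peak_id`` values ordered by (chrom, start).
    """
    rows = []
    for chrom, sub in peaks.groupby("chrom", sort=True):
        ivs = sub[["start", "end"]].sort_values(["start", "end"]).to_numpy()
        cur_s, cur_e = None, None
        for s, e in ivs:
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s < cur_e:  # >= 1 bp overlap; book-ended peaks stay separate
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    out["peak_id"] = [f"peak_{i:05d}" for i in range(len(out))]
    return out[["peak_id", "chrom", "start", "end"]]


def assign_called(union: pd.DataFrame, sample_peaks: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Flag which union peaks are called in each sample (>= 1 bp overlap)."""
    frames = []
    for sample_id, peaks in sample_peaks.items():
        called = np.zeros(len(union), dtype=bool)
        for chrom, sub in peaks.groupby("chrom"):
            u_mask = union["chrom"] == chrom
            u_start = union.loc[u_mask, "start"].to_numpy()
            u_end = union.loc[u_mask, "end"].to_numpy()
            hit = np.zeros(u_start.size, dtype=bool)
            for s, e in sub[["start", "end"]].to_numpy():
                hit |= (u_start < e) & (s < u_end)
            called[u_mask.to_numpy()] |= hit
        frames.append(
            pd.DataFrame(
                {"peak_id": union["peak_id"], "sample_id": sample_id, "called": called}
            )
        )
    return pd.concat(frames, ignore_index=True)


def assign_peak_ids(union: pd.DataFrame, intervals: pd.DataFrame) -> pd.DataFrame:
    """Attach the union ``peak_id`` containing each interval's midpoint.

    Intervals whose midpoint falls in no union peak get a NaN id.
    """
    out = intervals.copy()
    out["peak_id"] = pd.NA
    mid = (out["start"] + out["end"]) // 2
    for chrom, usub in union.groupby("chrom"):
        u_start = usub["start"].to_numpy()
        u_end = usub["end"].to_numpy()
        u_ids = usub["peak_id"].to_numpy()
        mask = (out["chrom"] == chrom).to_numpy()
        m = mid[mask].to_numpy()
        idx = np.searchsorted(u_start, m, side="right") - 1
        ok = (idx >= 0) & (m < u_end[np.clip(idx, 0, u_end.size - 1)])
        ids = np.where(ok, u_ids[np.clip(idx, 0, u_ids.size - 1)], None)
        out.loc[mask, "peak_id"] = ids
    return out


def peak_window_counts(
    peaks: pd.DataFrame,
    window: int,
    chrom_lengths: Mapping[str, int],
) -> pd.DataFrame:
    """Median peak count per window x timepoint, across replicates.

    ``peaks`` is long form (chrom, start, end, timepoint, replicate); a
    peak counts toward the window containing its midpoint.
    """
    df = peaks.copy()
    df["window"] = ((df["start"] + df["end"]) // 2) // window
    counts = (
        df.groupby(["chrom", "window", "timepoint", "replicate"], sort=True)
        .size()
        .rename("n_peaks")
        .reset_index()
    )
    rows = []
    replicates = sorted(peaks["replicate"].unique())
    timepoints = sorted(peaks["timepoint"].unique())
    for chrom, length in chrom_lengths.items():
        n_windows = int(math.ceil(length / window))
        for w in range(n_windows):
            for tp in timepoints:
                sub = counts[
                    (counts["chrom"] == chrom)
                    & (counts["window"] == w)
                    & (counts["timepoint"] == tp)
                ]
                per_rep = [
                    int(sub.loc[sub["replicate"] == r, "n_peaks"].sum())
                    for r in replicates
                ]
                rows.append(
                    {
                        "chrom": chrom,
                        "start": w * window,
                        "end": min((w + 1) * window, length),
                        "timepoint": tp,
                        "median_peaks": float(np.median(per_rep)),
                    }
                )
    return pd.DataFrame(rows)


def aged_enrichment(aged_count: float, adult_count: float) -> Tuple[float, float]:
    """Aged / (aged + adult) peak fraction with one-sided exact binomial p.

    The null assumes an equal number of peaks between timepoints
    (p = 0.5); p = P(X >= aged). Half-integer medians are rounded
    half-up to the nearest count before testing.
    """
    a = int(math.floor(aged_count + 0.5))
    b = int(math.floor(adult_count + 0.5))
    n = a + b
    if n == 0:
        return float("nan"), 1.0
    return a / n, binom_pvalue_greater(a, n, 0.5)


def window_aged_enrichment(window_counts: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`aged_enrichment` per window to adult/aged median counts."""
    wide = window_counts.pivot_table(
        index=["chrom", "start", "end"],
        columns="timepoint",
        values="median_peaks",
    ).reset_index()
    ratios, pvals = [], []
    for row in wide.itertuples():
        ratio, p = aged_enrichment(getattr(row, "aged", 0.0), getattr(row, "adult", 0.0))
        ratios.append(ratio)
        pvals.append(p)
    wide["enrichment_aged"] = ratios
    wide["p_value"] = pvals
    return wide.rename(columns={"adult": "median_peaks_adult", "aged": "median_peaks_aged"})


def compartment_fraction_test(
    counts: Mapping[str, Mapping[str, int]]
) -> Dict[str, FisherResult]:
    """Per-compartment Fisher test of adult vs aged peak fractions.

    ``counts`` maps compartment (autosomes / Xa / Xi) -> {timepoint:
    peak count}. Each compartment is tested against the rest in a 2x2
    (compartment vs rest) x (adult vs aged) table, two-sided.
    """
    compartments = list(counts)
    tot_adult = sum(counts[c].get("adult", 0) for c in compartments)
    tot_aged = sum(counts[c].get("aged", 0) for c in compartments)
    out = {}
    for c in compartments:
        a = counts[c].get("adult", 0)
        b = counts[c].get("aged", 0)
        out[c] = fisher_exact_2x2(a, b, tot_adult - a, tot_aged - b)
    return out


def summarize_peak_allelic(
    allele_counts: pd.DataFrame,
    total_cutoff: int,
) -> pd.DataFrame:
    """Per peak x timepoint median AR over informative replicates.

    ``allele_counts`` is long form (peak_id, timepoint, replicate,
    maternal, paternal). A replicate is informative when its total
    allele-assigned reads reach ``total_cutoff``.
    """
    df = allele_counts.copy()
    df["total"] = df["maternal"] + df["paternal"]
    df["ar"] = compute_ar(df["maternal"].to_numpy(), df["paternal"].to_numpy())
    df["ar_informative"] = np.where(df["total"] >= total_cutoff, df["ar"], np.nan)
    out = (
        df.groupby(["peak_id", "timepoint"], sort=True)
        .agg(
            n_replicates=("ar", "size"),
            n_informative=("ar_informative", "count"),
            median_ar=("ar_informative", "median"),
            total_reads=("total", "sum"),
        )
        .reset_index()
    )
    return out


def call_peak_escape(
    peak_summary: pd.DataFrame,
    called: pd.DataFrame,
    sample_timepoints: Mapping[str, str],
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Escape status per peak x timepoint plus adult→aged dynamics.

    A peak escapes (is biallelically accessible) when its median AR is at
    or below the escape cutoff; informativeness requires at least one
    replicate above the bulk read cutoff. Dynamics: ``de_novo_aged`` =
    called only in aged samples and escaping there; ``switch_to_biallelic``
    = called at both timepoints, Xa-specific in adult, escaping in aged;
    everything else is ``stable``.
    """
    summ = peak_summary.copy()
    cutoff = config.escape_ar_cutoff
    status = np.full(len(summ), NOT_INFORMATIVE, dtype=object)
    informative = summ["n_informative"].to_numpy() >= 1
    escape = (summ["median_ar"] <= cutoff).to_numpy() & informative
    status[informative & escape] = ESCAPE_PEAK
    status[informative & ~escape] = XA_SPECIFIC
    summ["escape_status"] = status

    called = called.copy()
    called["timepoint"] = called["sample_id"].map(dict(sample_timepoints))
    called_any = (
        called.groupby(["peak_id", "timepoint"])["called"].any().unstack(fill_value=False)
    )
    stat = summ.pivot_table(
        index="peak_id", columns="timepoint", values="escape_status", aggfunc="first"
    )
    dynamics = []
    for peak_id in stat.index:
        adult_called = bool(called_any.get("adult", pd.Series(dtype=bool)).get(peak_id, False))
        aged_called = bool(called_any.get("aged", pd.Series(dtype=bool)).get(peak_id, False))
        s_adult = stat.loc[peak_id].get("adult", NOT_INFORMATIVE)
        s_aged = stat.loc[peak_id].get("aged", NOT_INFORMATIVE)
        if aged_called and not adult_called and s_aged == ESCAPE_PEAK:
            dyn = DYN_DE_NOVO
        elif adult_called and aged_called and s_adult == XA_SPECIFIC and s_aged == ESCAPE_PEAK:
            dyn = DYN_SWITCH
        else:
            dyn = DYN_STABLE
        dynamics.append({"peak_id": peak_id, "dynamics": dyn})
    return summ.merge(pd.DataFrame(dynamics), on="peak_id", how="left")


def high_confidence_shifts(
    peak_summary: pd.DataFrame,
    called: pd.DataFrame,
    sample_timepoints: Mapping[str, str],
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Peaks called in every aged replicate with ΔAR >= the cutoff.

    ΔAR = median AR adult − median AR aged; both medians must be defined.
    """
    called = called.copy()
    called["timepoint"] = called["sample_id"].map(dict(sample_timepoints))
    aged_called = (
        called[called["timepoint"] == "aged"].groupby("peak_id")["called"].all()
    )
    ar = peak_summary.pivot_table(
        index="peak_id", columns="timepoint", values="median_ar"
    )
    out = []
    for peak_id in ar.index:
        if not bool(aged_called.get(peak_id, False)):
            continue
        ar_adult = ar.loc[peak_id].get("adult", np.nan)
        ar_aged = ar.loc[peak_id].get("aged", np.nan)
        d = ar_adult - ar_aged
        if not np.isnan(d) and d >= config.delta_ar_cutoff:
            out.append(
                {
                    "peak_id": peak_id,
                    "median_ar_adult": ar_adult,
                    "median_ar_aged": ar_aged,
                    "delta_ar": d,
                }
            )
    return pd.DataFrame(out, columns=["peak_id", "median_ar_adult", "median_ar_aged", "delta_ar"])


def annotate_peaks(
    peaks: pd.DataFrame,
    escapee_positions: Sequence[int],
    cres: Sequence[RegulatoryElement],
    proximity: int = 200_000,
) -> pd.DataFrame:
    """Distance to the nearest escapee and regulatory class per peak.

    Distance is measured from the peak midpoint to the nearest escapee
    position; overlap with cCREs resolves by priority promoter >
    enhancer (proximal or distal) > intergenic, with CTCF-only overlap
    mapping to intergenic.
    """
    from .windows import nearest_distance

    mid = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    if len(list(escapee_positions)) == 0:
        dist = np.full(mid.size, np.nan)
        within = np.zeros(mid.size, dtype=bool)
    else:
        dist, _ = nearest_distance(mid, escapee_positions, proximity)
        within = dist <= proximity
    classes = []
    for row, m in zip(peaks.itertuples(), mid):
        hit = {"promoter": False, "enhancer": False}
        for cre in cres:
            if cre.chrom != row.chrom:
                continue
            if row.start < cre.end and cre.start < row.end:
                if cre.cre_class == "promoter":
                    hit["promoter"] = True
                elif cre.cre_class in ("proximal_enhancer", "distal_enhancer"):
                    hit["enhancer"] = True
        if hit["promoter"]:
            classes.append("promoter")
        elif hit["enhancer"]:
            classes.append("enhancer")
        else:
            classes.append("intergenic")
    out = peaks.copy()
    out["distance_to_nearest_escapee"] = dist
    out["within_proximity"] = within
    out["cre_class"] = classes
    return out
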
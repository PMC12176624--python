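"""Gene-level allelic ratios from per-SNP allele counts.

The allelic ratio (AR) of a feature is maternal / (maternal + paternal)
read counts over its SNP-overlapping reads. In the skewed cross the
maternal (BL6) X is always active, so AR 1 means exclusive active-X
expression and AR below 1 means a fraction of transcripts originates from
the inactive paternal X.
"""

from __future__ import annotations

import warnings
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps


def compute_ar(maternal, paternal):
    """AR = maternal / (maternal + paternal); NaN when both are zero.

    Accepts scalars or aligned arrays.
    """
    m = np.asarray(maternal, dtype=float)
    p = np.asarray(paternal, dtype=float)
    total = m + p
    with np.errstate(invalid="ignore", divide="ignore"):
        ar = np.where(total > 0, m / total, np.nan)
    if ar.ndim == 0:
        return float(ar)
    return ar


def aggregate_gene_counts(
    snps: pd.DataFrame, genes: pd.DataFrame, minread: int = 1
) -> pd.DataFrame:
    """Sum SNP-level allele counts to gene x sample totals.

    A SNP contributes to a gene iff its position lies in [start, end)
    (0-based half-open) on the same chromosome. SNPs with fewer than
    ``minread`` total reads are dropped before summation. Every gene x
    sample combination is reported; genes with no retained SNP get (0, 0).
    Overlapping genes each receive the shared SNPs.
    """
    minread = max(int(minread), 1)
    samples = sorted(snps["sample_id"].unique())
    kept = snps[(snps["maternal"] + snps["paternal"]) >= minread]
    sample_codes = pd.Categorical(kept["sample_id"], categories=samples).codes
    frames = []
    n_samples = len(samples)
    for chrom, gsub in genes.groupby("chrom", sort=True):
        mask = kept["chrom"].to_numpy() == chrom
        pos = kept.loc[mask, "pos"].to_numpy()
        order = np.argsort(pos, kind="mergesort")
        pos = pos[order]
        mat = kept.loc[mask, "maternal"].to_numpy()[order]
        pat = kept.loc[mask, "paternal"].to_numpy()[order]
        codes = sample_codes[mask][order]
        for row in gsub.itertuples():
            lo = np.searchsorted(pos, row.start, side="left")
            hi = np.searchsorted(pos, row.end, side="left")
            m_tot = np.bincount(codes[lo:hi], weights=mat[lo:hi], minlength=n_samples)
            p_tot = np.bincount(codes[lo:hi], weights=pat[lo:hi], minlength=n_samples)
            frames.append(
                pd.DataFrame(
                    {
                        "gene_id": row.gene_id,
                        "sample_id": samples,
                        "maternal": m_tot.astype(int),
                        "paternal": p_tot.astype(int),
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=["gene_id", "sample_id", "maternal", "paternal"])
    return pd.concat(frames, ignore_index=True)


def summarize_allelic(
    gene_counts: pd.DataFrame,
    meta: pd.DataFrame,
    total_cutoff: int = 20,
    min_informative_samples: int = 2,
) -> pd.DataFrame:
    """Per gene x group x timepoint (x sex) allelic summary.

    A replicate is informative when its total SNP-overlapping reads over
    the gene reach ``total_cutoff``; the reported ``median_ar`` is the
    median over informative replicates and is NaN when fewer than
    ``min_informative_samples`` replicates are informative.
    """
    df = gene_counts.merge(
        meta[["sample_id", "group", "sex", "timepoint"]], on="sample_id", how="inner"
    )
    df["total"] = df["maternal"] + df["paternal"]
    df["ar"] = compute_ar(df["maternal"].to_numpy(), df["paternal"].to_numpy())
    df["informative"] = df["total"] >= total_cutoff

    df["ar_informative"] = np.where(df["informative"], df["ar"], np.nan)
    keys = ["gene_id", "group", "sex", "timepoint"]
    out = (
        df.groupby(keys, sort=True)
        .agg(
            n_samples=("ar", "size"),
            n_informative=("informative", "sum"),
            median_ar=("ar_informative", "median"),
            total_reads=("total", "sum"),
        )
        .reset_index()
    )
    out["n_informative"] = out["n_informative"].astype(int)
    out["informative"] = out["n_informative"] >= min_informative_samples
    out.loc[~out["informative"], "median_ar"] = np.nan
    return out


def per_sample_ars(
    gene_counts: pd.DataFrame, meta: pd.DataFrame, total_cutoff: int = 20
) -> pd.DataFrame:
    """Long table of per-replicate ARs with informativeness flags."""
    df = gene_counts.merge(meta, on="sample_id", how="inner")
    df["total"] = df["maternal"] + df["paternal"]
    df["ar"] = compute_ar(df["maternal"].to_numpy(), df["paternal"].to_numpy())
    df["informative"] = df["total"] >= total_cutoff
    return df


def compute_tpm(counts: pd.DataFrame, exonic_length: pd.Series) -> pd.DataFrame:
    """Transcripts per million from raw gene counts.

    ``counts`` is long-form (gene_id, sample_id, count); ``exonic_length``
    maps gene_id -> bp. TPM_g = (count_g / len_g) / sum_h(count_h / len_h)
    * 1e6 per sample, over the full provided gene universe.
    """
    df = counts.copy()
    lengths = df["gene_id"].map(exonic_length)
    if lengths.isna().any():
        missing = df.loc[lengths.isna(), "gene_id"].iloc[0]
        raise ValueError(f"gene {missing!r} has no exonic length")
    if (lengths <= 0).any():
        raise ValueError("exonic_length must be > 0 for every quantified gene")
    df["rate"] = df["count"] / lengths
    denom = df.groupby("sample_id")["rate"].transform("sum")
    zero = denom == 0
    if zero.any():
        warnings.warn("sample(s) with all-zero counts: TPM set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        df["tpm"] = np.where(zero, 0.0, df["rate"] / denom * 1e6)
    return df[["gene_id", "sample_id", "count", "tpm"]].rename(
        columns={"count": "raw_count"}
    )


def sex_fold_change(female_tpms: Sequence[float], male_tpms: Sequence[float]) -> float:
    """median(female TPM) / median(male TPM); NaN when the male median is 0."""
    f = np.asarray(list(female_tpms), dtype=float)
    m = np.asarray(list(male_tpms), dtype=float)
    if f.size == 0 or m.size == 0:
        raise ValueError("both sexes need at least one TPM value")
    med_m = float(np.median(m))
    if med_m == 0:
        return float("nan")
    return float(np.median(f) / med_m)


def correlate_ar_fc(
    pairs: Sequence[Tuple[float, float]]
) -> Tuple[float, float]:
    """Spearman correlation between median AR and sex fold change.

    Returns (rho, two-sided p); rho is NaN for constant input.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 (AR, fold-change) pairs")
    if np.isnan(arr).any():
        raise ValueError("undefined values in correlation input")
    if np.all(arr[:, 0] == arr[0, 0]) or np.all(arr[:, 1] == arr[0, 1]):
        return float("nan"), float("nan")
    res = sps.spearmanr(arr[:, 0], arr[:, 1])
    return float(res.statistic), float(res.pvalue)
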
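"""Per-cell X-inactivation status and pseudobulk escape analysis.

Each cell's chromosome-wide allelic ratio over X-linked SNP-overlapping
reads (excluding configured intervals such as the Xist locus) assigns its
active X: AR at or below the low threshold means the paternal (CAST) X is
active, at or above the high threshold the maternal (BL6) X; in between
the cell reads as biallelic, and cells below the read floor stay
unassigned. Boundary ties go to the monoallelic call. Pseudobulk escape
calling pools allele counts over cells sharing the selected active-X
strain within each cluster.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
import pandas as pd

from .allelic import compute_ar
from .calling import call_table
from .config import AnalysisConfig

XA_BL6 = "BL6_Xa"
XA_CAST = "CAST_Xa"
XA_BIALLELIC = "biallelic"
XA_UNASSIGNED = "unassigned"


def aggregate_cell_snp_counts(
    snp_counts: pd.DataFrame,
    exclusion_intervals: Sequence[Tuple[str, int, int]] = (),
) -> pd.DataFrame:
    """Sum per-cell per-SNP counts to per-cell X totals, masking intervals.

    ``snp_counts`` columns: barcode, chrom, pos, maternal, paternal.
    """
    df = snp_counts.copy()
    keep = np.ones(len(df), dtype=bool)
    for chrom, start, end in exclusion_intervals:
        keep &= ~(
            (df["chrom"] == chrom) & (df["pos"] >= start) & (df["pos"] < end)
        ).to_numpy()
    barcodes = sorted(df["barcode"].unique())
    df = df[keep]
    out = (
        df.groupby("barcode", sort=True)[["maternal", "paternal"]]
        .sum()
        .reindex(barcodes, fill_value=0)  # fully masked cells keep a row
        .reset_index()
    )
    out["x_total"] = out["maternal"] + out["paternal"]
    out = out.rename(columns={"maternal": "x_maternal"}).drop(columns=["paternal"])
    return out


def cell_x_ar(x_maternal, x_total):
    """Chromosome-wide per-cell AR; NaN when the cell has no X reads."""
    m = np.asarray(x_maternal, dtype=float)
    t = np.asarray(x_total, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ar = np.where(t > 0, m / t, np.nan)
    return float(ar) if ar.ndim == 0 else ar


def classify_xa(ar_x, x_total, config: AnalysisConfig):
    """Active-X status per cell from chromosome-wide AR and read depth."""
    ar = np.atleast_1d(np.asarray(ar_x, dtype=float))
    total = np.atleast_1d(np.asarray(x_total, dtype=float))
    status = np.full(ar.size, XA_BIALLELIC, dtype=object)
    status[ar <= config.cell_ar_low] = XA_CAST
    status[ar >= config.cell_ar_high] = XA_BL6
    status[np.isnan(ar)] = XA_UNASSIGNED
    status[total < config.cell_min_x_reads] = XA_UNASSIGNED
    if np.isscalar(ar_x) or np.ndim(ar_x) == 0:
        return str(status[0])
    return status


def classify_cells(cells: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Attach ar_x and xa_status to a per-cell table (x_maternal, x_total)."""
    out = cells.copy()
    out["ar_x"] = cell_x_ar(out["x_maternal"].to_numpy(), out["x_total"].to_numpy())
    out["xa_status"] = classify_xa(
        out["ar_x"].to_numpy(), out["x_total"].to_numpy(), config
    )
    return out


def build_pseudobulk(
    cell_gene_counts: pd.DataFrame,
    cells: pd.DataFrame,
    config: AnalysisConfig,
    xa_filter: str = XA_BL6,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Pool per-gene allele counts over same-active-X cells per cluster.

    ``cell_gene_counts``: (barcode, gene_id, maternal, paternal);
    ``cells``: (barcode, cluster, timepoint, xa_status). Clusters must
    exceed ``cluster_min_cells`` qualifying cells at every timepoint to
    be analyzed (strict greater-than). Returns (pseudobulk counts per
    cluster x timepoint x gene, cluster cell-count table).
    """
    selected = cells[cells["xa_status"] == xa_filter]
    n_cells = (
        selected.groupby(["cluster", "timepoint"], sort=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    timepoints = sorted(cells["timepoint"].unique())
    wide = n_cells.pivot_table(
        index="cluster", columns="timepoint", values="n_cells", fill_value=0
    ).reindex(columns=timepoints, fill_value=0)
    kept_clusters = wide.index[(wide > config.cluster_min_cells).all(axis=1)]
    pool = cell_gene_counts.merge(
        selected[selected["cluster"].isin(kept_clusters)][
            ["barcode", "cluster", "timepoint"]
        ],
        on="barcode",
        how="inner",
    )
    pseudo = (
        pool.groupby(["cluster", "timepoint", "gene_id"], sort=True)[
            ["maternal", "paternal"]
        ]
        .sum()
        .reset_index()
    )
    n_cells["analyzed"] = n_cells["cluster"].isin(kept_clusters)
    return pseudo, n_cells


def pseudobulk_escape_calls(
    pseudobulk: pd.DataFrame, config: AnalysisConfig
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Escape calling on pseudobulk allele counts.

    Pseudobulk has a single pooled observation per cluster x timepoint, so
    a gene is informative when its pooled total reaches the pseudobulk
    read cutoff. There is no male counterpart; the configured exclusion
    list is still applied.
    """
    df = pseudobulk.copy()
    df["total"] = df["maternal"] + df["paternal"]
    df["ar"] = compute_ar(df["maternal"].to_numpy(), df["paternal"].to_numpy())
    summary = pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "group": df["cluster"],
            "timepoint": df["timepoint"],
            "n_samples": 1,
            "n_informative": (df["total"] >= config.total_read_cutoff_pseudobulk).astype(int),
            "median_ar": np.where(
                df["total"] >= config.total_read_cutoff_pseudobulk, df["ar"], np.nan
            ),
            "total_reads": df["total"],
            "informative": df["total"] >= config.total_read_cutoff_pseudobulk,
        }
    )
    cfg = config.model_copy(update={"min_informative_samples": 1})
    return call_table(summary, None, cfg)


def composition_shift(cells: pd.DataFrame) -> pd.DataFrame:
    """Cell-type proportions per timepoint and their aged − adult delta."""
    counts = (
        cells.groupby(["cluster", "timepoint"], sort=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    totals = counts.groupby("timepoint")["n_cells"].transform("sum")
    if (totals == 0).any():
        raise ValueError("timepoint with zero cells")
    counts["proportion"] = counts["n_cells"] / totals
    wide = counts.pivot_table(
        index="cluster", columns="timepoint", values="proportion", fill_value=0.0
    ).reset_index()
    if "adult" in wide.columns and "aged" in wide.columns:
        wide["delta"] = wide["aged"] - wide["adult"]
    return wide
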
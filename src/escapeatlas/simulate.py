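"""Synthetic allele-specific datasets with planted ground truth.

The generator emulates the designs of a skewed-XCI F1 hybrid aging study:
bulk organ RNA across four life stages and both sexes, random-XCI single
cells with strain skew, and allelic ATAC peaks with aging-induced opening
of the inactive X at distal regions.

Noise model. Per-gene totals are gamma-Poisson (negative binomial)
dispersed around the target depth and split across the gene's SNPs;
paternal (inactive-X) reads are beta-binomial with mean equal to the true
Xi expression fraction and intra-class correlation ``overdispersion_rho``,
the standard overdispersion model for allelic imbalance. Silenced genes
leak a small Xi fraction (``leak_epsilon``); male samples carry a single
maternal X and emit no paternal reads unless a gene is planted as
mapping-biased.

Escape truth uses a two-level model: a gene is globally escape-prone
(constitutive) or aging-susceptible, and expresses that propensity in each
organ with a fixed penetrance. This reproduces both the per-organ escape
rates and the size of the cross-organ union of escapees, which a purely
per-organ-independent model cannot do at the same time. Aging-susceptible
genes are placed with probability ``distal_bias_w`` in the distal
head/tail regions of the chromosome.

All randomness flows from one :class:`numpy.random.Generator` seeded by
``SimConfig.seed``; identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .config import MOUSE_CHRX_LENGTH

ORGANS = ("brain", "heart", "kidney", "liver", "lung", "muscle", "spleen")
EMBRYONIC_ORGANS = ("brain", "heart", "kidney", "liver", "lung")
ADULT_TIMEPOINTS = ("young", "adult", "aged")

#: Cardiac cell clusters with (adult, aged) composition, emulating the
#: aging heart: cardiomyocytes shrink, fibroblasts expand.
DEFAULT_CELL_CLUSTERS: Dict[str, Tuple[float, float]] = {
    "cardiomyocyte": (0.304, 0.250),
    "fibroblast": (0.220, 0.323),
    "endothelial": (0.155, 0.140),
    "macrophage": (0.120, 0.110),
    "pericyte": (0.075, 0.062),
    "smooth_muscle": (0.040, 0.035),
    "other": (0.086, 0.080),
}


class SimConfig(BaseModel):
    """Parameters of the synthetic study; defaults are the study regime."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    seed: int
    n_genes: int = 400
    chrom_length: int = MOUSE_CHRX_LENGTH
    chrom: str = "chrX"
    snps_per_gene_mean: float = 5.0
    depth_mean: float = 200.0
    depth_shape: float = 5.0
    overdispersion_rho: float = 0.02
    baseline_escape_frac: float = 0.035
    escape_sharing: float = 0.64
    xi_fraction_range: Tuple[float, float] = (0.10, 0.50)
    leak_epsilon: float = 0.005
    aging_gain_frac: float = 0.031
    aging_sharing: float = 0.372
    distal_bias_w: float = 0.8
    distal_head: int = 20_000_000
    distal_tail: int = 40_000_000
    n_replicates: int = 3
    organs: Tuple[str, ...] = ORGANS
    embryonic_organs: Tuple[str, ...] = EMBRYONIC_ORGANS
    n_male_bias_genes: int = 0
    male_bias_fraction: float = 0.15
    # single-cell design
    cell_n_adult: int = 2000
    cell_n_aged: int = 1500
    cell_skew_cast_xa: float = 0.6
    cell_x_depth_mean: float = 50.0
    # allelic ATAC design
    atac_n_background: int = 300
    atac_n_opening: int = 30
    atac_n_replicates: int = 2
    atac_depth_mean: float = 100.0
    atac_background_leak: float = 0.03
    atac_opening_xi_range: Tuple[float, float] = (0.2, 0.5)
    atac_denovo_frac: float = 0.5
    atac_near_escapee_frac: float = 0.7

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        for name in (
            "overdispersion_rho",
            "baseline_escape_frac",
            "escape_sharing",
            "leak_epsilon",
            "aging_gain_frac",
            "aging_sharing",
            "distal_bias_w",
            "cell_skew_cast_xa",
            "atac_background_leak",
            "atac_denovo_frac",
            "atac_near_escapee_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.overdispersion_rho >= 1.0:
            raise ValueError("overdispersion_rho must be < 1")
        lo, hi = self.xi_fraction_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("xi_fraction_range must lie within (0, 1)")
        if self.distal_head + self.distal_tail >= self.chrom_length:
            raise ValueError("distal regions exceed the chromosome")
        return self


@dataclass
class SimBulk:
    """Bulk simulation output: observations plus planted truth."""

    snp_counts: pd.DataFrame
    genes: pd.DataFrame
    meta: pd.DataFrame
    truth: pd.DataFrame  # gene_id x group x timepoint: is_escape, xi_fraction
    config: SimConfig


@dataclass
class SimCells:
    cells: pd.DataFrame  # barcode, cluster, timepoint, x_maternal, x_total, true_xa
    cell_gene_counts: pd.DataFrame  # barcode, gene_id, maternal, paternal
    gene_truth: pd.DataFrame  # gene_id, timepoint, is_escape, xi_fraction
    config: SimConfig


@dataclass
class SimAtac:
    sample_peaks: Dict[str, pd.DataFrame]  # sample_id -> called peak BED
    allele_counts: pd.DataFrame  # chrom, start, end, timepoint, replicate, maternal, paternal
    truth: pd.DataFrame  # chrom, start, end, kind (background/de_novo/switch), is_opening
    sample_timepoints: Dict[str, str]
    config: SimConfig


def _beta_binomial(rng: np.random.Generator, n: np.ndarray, mean: np.ndarray, rho: float) -> np.ndarray:
    """Beta-binomial draws; degenerate means and rho = 0 reduce to binomial."""
    mean = np.asarray(mean, dtype=float)
    n = np.asarray(n)
    if rho <= 0.0:
        return rng.binomial(n, mean)
    p = np.array(mean, dtype=float)
    inner = (mean > 0) & (mean < 1)
    if inner.any():
        a = mean[inner] * (1.0 - rho) / rho
        b = (1.0 - mean[inner]) * (1.0 - rho) / rho
        p[inner] = rng.beta(a, b)
    return rng.binomial(n, p)


def _sample_positions(
    rng: np.random.Generator,
    n: int,
    chrom_length: int,
    head: int,
    tail: int,
    distal_prob: float,
) -> np.ndarray:
    """Positions from w * Uniform(head ∪ tail) + (1 − w) * Uniform(middle)."""
    distal = rng.random(n) < distal_prob
    pos = np.empty(n, dtype=np.int64)
    n_distal = int(distal.sum())
    if n_distal:
        in_head = rng.random(n_distal) < head / (head + tail)
        head_pos = rng.integers(0, head, size=n_distal)
        tail_pos = rng.integers(chrom_length - tail, chrom_length, size=n_distal)
        pos[distal] = np.where(in_head, head_pos, tail_pos)
    n_mid = n - n_distal
    if n_mid:
        pos[~distal] = rng.integers(head, chrom_length - tail, size=n_mid)
    return pos


def simulate_bulk(config: SimConfig) -> SimBulk:
    """Bulk organ design: organs x timepoints x sexes x replicates.

    Embryonic samples are female-only over the embryonic organ panel;
    young/adult/aged samples cover both sexes over the full panel.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    lo, hi = config.xi_fraction_range

    # --- gene roles and placement
    p_base = min(config.baseline_escape_frac / config.escape_sharing, 1.0)
    p_aging = min(config.aging_gain_frac / config.aging_sharing, 1.0 - p_base)
    roles = rng.choice(
        ["baseline", "aging", "silenced"],
        size=n,
        p=[p_base, p_aging, 1.0 - p_base - p_aging],
    )
    # genes occupy disjoint slots so no two genes share SNPs and the
    # planted per-gene truth is identifiable from counts
    max_span = 50_000
    slot_w = config.chrom_length // n
    if slot_w <= max_span:
        raise ValueError("n_genes too large for non-overlapping placement")
    head_slots = np.arange(config.distal_head // slot_w)
    tail_slots = np.arange(
        -(-(config.chrom_length - config.distal_tail) // slot_w), n
    )
    distal_pool = list(np.concatenate([head_slots, tail_slots]))
    middle_pool = sorted(set(range(n)) - set(distal_pool))
    rng.shuffle(distal_pool)
    rng.shuffle(middle_pool)
    aging_mask = roles == "aging"
    slot = np.empty(n, dtype=np.int64)
    for i in np.flatnonzero(aging_mask):
        go_distal = rng.random() < config.distal_bias_w
        if go_distal and distal_pool:
            slot[i] = distal_pool.pop()
        elif middle_pool:
            slot[i] = middle_pool.pop()
        else:
            slot[i] = distal_pool.pop()
    remaining = distal_pool + middle_pool
    rng.shuffle(remaining)
    for j, i in enumerate(np.flatnonzero(~aging_mask)):
        slot[i] = remaining[j]
    pos = slot * slot_w + rng.integers(0, slot_w - max_span, size=n)
    order = np.argsort(pos, kind="mergesort")
    pos, roles = pos[order], roles[order]
    span = rng.integers(5_000, max_span, size=n)
    end = pos + span
    exonic = rng.integers(500, 10_000, size=n)
    gene_ids = np.array([f"gene_{i:04d}" for i in range(n)])
    xi_frac = rng.uniform(lo, hi, size=n)
    n_snps = 1 + rng.poisson(max(config.snps_per_gene_mean - 1.0, 0.0), size=n)

    bias_idx = np.array([], dtype=int)
    if config.n_male_bias_genes > 0:
        silenced_idx = np.flatnonzero(roles == "silenced")
        bias_idx = rng.choice(
            silenced_idx, size=min(config.n_male_bias_genes, silenced_idx.size), replace=False
        )

    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": config.chrom,
            "start": pos,
            "end": end,
            "strand": "+",
            "exonic_length": exonic,
        }
    )

    # --- per-organ penetrance of the global propensity
    organs = list(config.organs)
    escapes_base = (rng.random((n, len(organs))) < config.escape_sharing) & (
        roles == "baseline"
    )[:, None]
    escapes_aging = (rng.random((n, len(organs))) < config.aging_sharing) & (
        roles == "aging"
    )[:, None]

    truth_rows = []
    xi_by_group_tp = {}
    for oi, organ in enumerate(organs):
        for tp in ("embryonic",) + ADULT_TIMEPOINTS:
            if tp == "embryonic" and organ not in config.embryonic_organs:
                continue
            esc = escapes_base[:, oi] | (escapes_aging[:, oi] & (tp == "aged"))
            xi_vec = np.where(esc, xi_frac, config.leak_epsilon)
            xi_by_group_tp[(organ, tp)] = xi_vec
            truth_rows.append(
                pd.DataFrame(
                    {
                        "gene_id": gene_ids,
                        "group": organ,
                        "timepoint": tp,
                        "is_escape": esc,
                        "xi_fraction": xi_vec,
                        "role": roles,
                    }
                )
            )
    truth = pd.concat(truth_rows, ignore_index=True)

    # --- samples
    meta_rows = []
    for organ in organs:
        for tp in ("embryonic",) + ADULT_TIMEPOINTS:
            if tp == "embryonic":
                if organ not in config.embryonic_organs:
                    continue
                sexes = ("female",)
            else:
                sexes = ("female", "male")
            for sex in sexes:
                for rep in range(1, config.n_replicates + 1):
                    meta_rows.append(
                        {
                            "sample_id": f"{organ}_{tp}_{sex}_r{rep}",
                            "group": organ,
                            "sex": sex,
                            "timepoint": tp,
                            "replicate": rep,
                        }
                    )
    meta = pd.DataFrame(meta_rows)

    # --- SNP placement and counts
    snp_gene = np.repeat(np.arange(n), n_snps)
    snp_pos = rng.integers(pos[snp_gene], end[snp_gene])

    male_bias = np.zeros(n)
    male_bias[bias_idx] = config.male_bias_fraction

    chunks = []
    for s in meta.itertuples():
        if s.sex == "female":
            mean_frac = xi_by_group_tp[(s.group, s.timepoint)]
        else:
            mean_frac = male_bias
        rate = rng.gamma(config.depth_shape, config.depth_mean / config.depth_shape, size=n)
        lam = rate[snp_gene] / n_snps[snp_gene]
        totals = rng.poisson(lam)
        # one beta draw per gene (shared across its SNPs) keeps the
        # gene-level counts beta-binomial
        if config.overdispersion_rho > 0:
            p_gene = np.array(mean_frac, dtype=float)
            inner = (mean_frac > 0) & (mean_frac < 1)
            if inner.any():
                rho = config.overdispersion_rho
                a = mean_frac[inner] * (1 - rho) / rho
                b = (1 - mean_frac[inner]) * (1 - rho) / rho
                p_gene[inner] = rng.beta(a, b)
        else:
            p_gene = mean_frac
        paternal = rng.binomial(totals, p_gene[snp_gene])
        chunks.append(
            pd.DataFrame(
                {
                    "chrom": config.chrom,
                    "pos": snp_pos,
                    "sample_id": s.sample_id,
                    "maternal": totals - paternal,
                    "paternal": paternal,
                }
            )
        )
    snp_counts = pd.concat(chunks, ignore_index=True)
    return SimBulk(snp_counts, genes, meta, truth, config)


def simulate_cells(config: SimConfig) -> SimCells:
    """Single-cell design: random XCI with strain skew, two timepoints."""
    rng = np.random.default_rng(config.seed + 1_000_003)
    n = config.n_genes
    gene_ids = np.array([f"gene_{i:04d}" for i in range(n)])
    roles = rng.choice(
        ["baseline", "aging", "silenced"],
        size=n,
        p=[
            config.baseline_escape_frac,
            config.aging_gain_frac,
            1.0 - config.baseline_escape_frac - config.aging_gain_frac,
        ],
    )
    lo, hi = config.xi_fraction_range
    xi = rng.uniform(lo, hi, size=n)
    gene_truth = pd.concat(
        [
            pd.DataFrame(
                {
                    "gene_id": gene_ids,
                    "timepoint": tp,
                    "is_escape": (roles == "baseline")
                    | ((roles == "aging") & (tp == "aged")),
                }
            )
            for tp in ("adult", "aged")
        ],
        ignore_index=True,
    )
    gene_truth["xi_fraction"] = np.where(
        gene_truth["is_escape"],
        np.tile(xi, 2),
        config.leak_epsilon,
    )

    weights = rng.dirichlet(np.ones(n))
    clusters = list(DEFAULT_CELL_CLUSTERS)
    props = {
        "adult": np.array([DEFAULT_CELL_CLUSTERS[c][0] for c in clusters]),
        "aged": np.array([DEFAULT_CELL_CLUSTERS[c][1] for c in clusters]),
    }
    cell_rows = []
    count_chunks = []
    for tp, n_cells in (("adult", config.cell_n_adult), ("aged", config.cell_n_aged)):
        frac = gene_truth.loc[gene_truth["timepoint"] == tp, "xi_fraction"].to_numpy()
        cl = rng.choice(clusters, size=n_cells, p=props[tp] / props[tp].sum())
        cast_xa = rng.random(n_cells) < config.cell_skew_cast_xa
        depth = rng.poisson(
            rng.gamma(5.0, config.cell_x_depth_mean / 5.0, size=n_cells)
        )
        barcodes = np.array([f"{tp}_cell_{i:05d}" for i in range(n_cells)])
        for i in range(n_cells):
            gene_counts = rng.multinomial(depth[i], weights)
            nz = np.flatnonzero(gene_counts)
            # the inactive X contributes each gene's Xi fraction; which
            # parental allele that is depends on the cell's active X
            inactive = rng.binomial(gene_counts[nz], frac[nz])
            if cast_xa[i]:
                maternal = inactive  # maternal BL6 is the inactive X
            else:
                maternal = gene_counts[nz] - inactive
            count_chunks.append(
                pd.DataFrame(
                    {
                        "barcode": barcodes[i],
                        "gene_id": gene_ids[nz],
                        "maternal": maternal,
                        "paternal": gene_counts[nz] - maternal,
                    }
                )
            )
            cell_rows.append(
                {
                    "barcode": barcodes[i],
                    "cluster": cl[i],
                    "timepoint": tp,
                    "x_maternal": int(maternal.sum()),
                    "x_total": int(depth[i]),
                    "true_xa": "CAST_Xa" if cast_xa[i] else "BL6_Xa",
                }
            )
    cells = pd.DataFrame(cell_rows)
    cell_gene_counts = (
        pd.concat(count_chunks, ignore_index=True)
        if count_chunks
        else pd.DataFrame(columns=["barcode", "gene_id", "maternal", "paternal"])
    )
    return SimCells(cells, cell_gene_counts, gene_truth, config)


def simulate_atac(
    config: SimConfig, escapee_positions: Optional[Sequence[int]] = None
) -> SimAtac:
    """Allelic ATAC design: adult/aged x replicates on one chromosome.

    Background peaks are uniformly placed and accessible only on the
    active X (AR near 1) at both timepoints. Planted opening peaks sit in
    the distal head/tail regions (optionally near supplied escapee
    positions) and become biallelic in aged samples; a ``de novo``
    subset is additionally not peak-called in adult samples.
    """
    rng = np.random.default_rng(config.seed + 2_000_003)
    L = config.chrom_length
    n_bg, n_open = config.atac_n_background, config.atac_n_opening
    slot_w = L // (4 * (n_bg + n_open))
    slots = rng.choice(L // slot_w - 1, size=n_bg + n_open, replace=False)
    starts = slots * slot_w + rng.integers(0, slot_w // 2, size=n_bg + n_open)
    widths = rng.integers(300, 1500, size=n_bg + n_open)

    # opening peaks go distal (and near escapees when provided)
    open_starts = _sample_positions(
        rng, n_open, L, config.distal_head, config.distal_tail, 1.0
    )
    if escapee_positions is not None and len(escapee_positions) > 0:
        esc = np.asarray(list(escapee_positions), dtype=np.int64)
        near = rng.random(n_open) < config.atac_near_escapee_frac
        anchor = esc[rng.integers(0, esc.size, size=n_open)]
        jitter = rng.integers(-150_000, 150_000, size=n_open)
        open_starts = np.where(
            near, np.clip(anchor + jitter, 0, L - 2_000), open_starts
        )
    starts[:n_open] = open_starts  # first n_open slots become opening peaks
    kinds = np.array(
        ["de_novo" if rng.random() < config.atac_denovo_frac else "switch" for _ in range(n_open)]
        + ["background"] * n_bg
    )
    ends = np.minimum(starts + widths, L)
    truth = pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": starts,
            "end": ends,
            "kind": kinds,
            "is_opening": kinds != "background",
        }
    ).sort_values("start", ignore_index=True)

    xi_lo, xi_hi = config.atac_opening_xi_range
    open_frac_aged = rng.uniform(xi_lo, xi_hi, size=len(truth))
    sample_timepoints: Dict[str, str] = {}
    sample_peaks: Dict[str, pd.DataFrame] = {}
    count_rows = []
    for tp in ("adult", "aged"):
        for rep in range(1, config.atac_n_replicates + 1):
            sid = f"{tp}_r{rep}"
            sample_timepoints[sid] = tp
            if tp == "adult":
                called_mask = truth["kind"].isin(["background", "switch"]).to_numpy()
            else:
                called_mask = np.ones(len(truth), dtype=bool)
            sample_peaks[sid] = truth.loc[called_mask, ["chrom", "start", "end"]].reset_index(
                drop=True
            )
            total = rng.poisson(
                rng.gamma(5.0, config.atac_depth_mean / 5.0, size=len(truth))
            )
            mean_frac = np.full(len(truth), config.atac_background_leak)
            if tp == "aged":
                opening = truth["is_opening"].to_numpy()
                mean_frac[opening] = open_frac_aged[opening]
            paternal = _beta_binomial(rng, total, mean_frac, config.overdispersion_rho)
            count_rows.append(
                pd.DataFrame(
                    {
                        "chrom": config.chrom,
                        "start": truth["start"],
                        "end": truth["end"],
                        "timepoint": tp,
                        "replicate": rep,
                        "maternal": total - paternal,
                        "paternal": paternal,
                    }
                )
            )
    allele_counts = pd.concat(count_rows, ignore_index=True)
    return SimAtac(sample_peaks, allele_counts, truth, sample_timepoints, config)


def evaluate_recovery(
    predicted: Sequence, truth: Sequence
) -> Dict[str, float]:
    """Precision/recall of a predicted id set against a planted truth set.

    Precision is NaN (undefined) when nothing was predicted; recall is
    NaN when the truth set is empty.
    """
    pred = set(predicted)
    true = set(truth)
    tp = len(pred & true)
    precision = tp / len(pred) if pred else float("nan")
    recall = tp / len(true) if true else float("nan")
    return {
        "n_predicted": len(pred),
        "n_true": len(true),
        "n_correct": tp,
        "precision": precision,
        "recall": recall,
    }
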
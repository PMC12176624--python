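"""Analysis configuration.

All thresholds used across the pipeline live in a single immutable
:class:`AnalysisConfig` object so a run is fully described by one mapping.
Defaults follow the allele-specific escape-detection workflow for the
skewed-XCI F1 hybrid cross (BL6 ΔXist × CAST): a gene escapes X inactivation
when its median allelic ratio (maternal / total) drops to ``escape_ar_cutoff``
or below, i.e. at least 10% of its expression originates from the inactive
paternal X.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

#: Mouse chrX length (GRCm38/mm10), bp.
MOUSE_CHRX_LENGTH = 171_031_299

#: Genes removed from escape calling: pseudoautosomal genes plus genes that
#: look biallelic in male (single-X) samples and are therefore false positives.
DEFAULT_EXCLUDED_GENES: Tuple[str, ...] = (
    "Mid1",
    "G530011O06Rik",
    "Gm39551",
    "Gm14719",
    "Armcx4",
    "Sms",
    "Llph-ps2",
)

TIMEPOINTS: Tuple[str, ...] = ("embryonic", "young", "adult", "aged")


class AnalysisConfig(BaseModel):
    """Thresholds and genomic constants for one analysis run.

    Units: AR-valued fields are dimensionless in [0, 1]; ``*_cutoff`` read
    fields are read counts; positional fields are bp on a 0-based half-open
    coordinate system.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    escape_ar_cutoff: float = 0.9
    minread: int = 1
    total_read_cutoff_bulk: int = 20
    total_read_cutoff_celltype: int = 10
    total_read_cutoff_pseudobulk: int = 20
    min_informative_samples: int = 2
    delta_ar_cutoff: float = 0.1
    cluster_max_gap: int = 2_500_000
    rna_window: int = 20_000_000
    rna_window_step: int = 10_000_000
    atac_window: int = 10_000_000
    distal_head: int = 20_000_000
    distal_tail: int = 40_000_000
    peak_proximity: int = 200_000
    cell_min_x_reads: int = 10
    cell_ar_low: float = 0.2
    cell_ar_high: float = 0.8
    cluster_min_cells: int = 50  # strict greater-than
    chrom_length: int = MOUSE_CHRX_LENGTH
    excluded_genes: Tuple[str, ...] = DEFAULT_EXCLUDED_GENES
    #: Intervals whose SNPs are masked before per-cell chromosome-wide AR
    #: (e.g. the Xist locus, which is expressed from the inactive X).
    exclusion_intervals: Tuple[Tuple[str, int, int], ...] = ()

    @model_validator(mode="after")
    def _check_invariants(self) -> "AnalysisConfig":
        if not 0.0 < self.escape_ar_cutoff < 1.0:
            raise ValueError("escape_ar_cutoff must lie strictly in (0, 1)")
        if not self.cell_ar_low < self.cell_ar_high:
            raise ValueError("cell_ar_low must be < cell_ar_high")
        for name in (
            "cluster_max_gap",
            "rna_window",
            "rna_window_step",
            "atac_window",
            "distal_head",
            "distal_tail",
            "peak_proximity",
            "chrom_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.distal_head + self.distal_tail >= self.chrom_length:
            raise ValueError("distal_head + distal_tail must be < chrom_length")
        for chrom, start, end in self.exclusion_intervals:
            if start >= end:
                raise ValueError(
                    f"exclusion interval {chrom}:{start}-{end} has start >= end"
                )
        return self


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a JSON or YAML mapping.

    Absent keys take defaults; unknown keys are rejected.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return AnalysisConfig(**data)


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    """Write a config as JSON (``.json``) or YAML (anything else)."""
    path = Path(path)
    data = config.model_dump()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
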
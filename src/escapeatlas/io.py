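"""Readers and writers for the tabular and interval formats the pipeline touches.

Conventions: all coordinates are 0-based half-open (BED); TSV files are
tab-separated, UTF-8, no quoting, with '#'-prefixed comment lines permitted.
Writers emit a fixed column order so output diffs are stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Union

import pandas as pd

SNP_COLUMNS = ["chrom", "pos", "sample_id", "maternal", "paternal"]
META_COLUMNS = ["sample_id", "group", "sex", "timepoint", "replicate"]

CRE_CLASSES = ("promoter", "proximal_enhancer", "distal_enhancer", "ctcf")


@dataclass(frozen=True)
class GeneModel:
    """One gene: span on the chromosome plus summed exonic length (bp)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    exonic_length: int = 0

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )
        if self.exonic_length <= 0:
            object.__setattr__(self, "exonic_length", self.end - self.start)


@dataclass(frozen=True)
class RegulatoryElement:
    """A candidate cis-regulatory element with its ENCODE-style class."""

    chrom: str
    start: int
    end: int
    cre_class: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"element {self.chrom}:{self.start}-{self.end} has start >= end"
            )
        if self.cre_class not in CRE_CLASSES:
            raise ValueError(
                f"unknown cCRE class {self.cre_class!r}; expected one of {CRE_CLASSES}"
            )


def _read_tsv(path: Union[str, Path], names: Sequence[str] | None = None) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=0 if names is None else None,
        names=list(names) if names is not None else None,
        dtype=str,
    )


def read_snp_counts(path: Union[str, Path]) -> pd.DataFrame:
    """Read a per-SNP allele count TSV (chrom, pos, sample_id, maternal, paternal).

    Counts must be non-negative integers; a malformed row raises with its
    line number.
    """
    df = _read_tsv(path)
    missing = [c for c in SNP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[SNP_COLUMNS].copy()
    for col in ("pos", "maternal", "paternal"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        if parsed.isna().any():
            line = int(parsed.index[parsed.isna()][0]) + 2  # header + 1-based
            raise ValueError(f"{path}:{line}: non-numeric value in column {col!r}")
        if (parsed % 1 != 0).any():
            line = int(parsed.index[parsed % 1 != 0][0]) + 2
            raise ValueError(f"{path}:{line}: non-integer value in column {col!r}")
        df[col] = parsed.astype(int)
    for col in ("maternal", "paternal"):
        if (df[col] < 0).any():
            line = int(df.index[df[col] < 0][0]) + 2
            raise ValueError(f"{path}:{line}: negative count in column {col!r}")
    return df


def write_snp_counts(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df[SNP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sample_meta(path: Union[str, Path]) -> pd.DataFrame:
    """Read sample metadata (sample_id, group, sex, timepoint, replicate)."""
    df = _read_tsv(path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[META_COLUMNS].copy()
    df["replicate"] = pd.to_numeric(df["replicate"]).astype(int)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")
    if (df["replicate"] < 1).any():
        raise ValueError(f"{path}: replicate numbers must be >= 1")
    bad_sex = set(df["sex"]) - {"female", "male"}
    if bad_sex:
        raise ValueError(f"{path}: unknown sex values {sorted(bad_sex)}")
    return df


def write_sample_meta(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df[META_COLUMNS].to_csv(path, sep="\t", index=False)


def read_intervals(
    path: Union[str, Path],
    with_class: bool = False,
    one_based: bool = False,
) -> Union[List[GeneModel], List[RegulatoryElement]]:
    """Read a BED-like interval file, sorted by (chrom, start).

    Without ``with_class`` rows become :class:`GeneModel` (columns: chrom,
    start, end, name[, exonic_length[, strand]]); with it they become
    :class:`RegulatoryElement` (columns: chrom, start, end, name, class).
    ``one_based`` converts inclusive 1-based starts to the internal 0-based
    half-open convention at the boundary.
    """
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        if one_based:
            start -= 1
        if start >= end:
            raise ValueError(
                f"{path}:{lineno}: interval {chrom}:{start}-{end} has start >= end"
            )
        if with_class:
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: class column (5) required")
            records.append(RegulatoryElement(chrom, start, end, fields[4]))
        else:
            name = fields[3] if len(fields) > 3 else f"feat_{lineno}"
            exonic = 0
            if len(fields) > 4 and fields[4] not in (".", ""):
                exonic = int(float(fields[4]))
            strand = fields[5] if len(fields) > 5 else "+"
            records.append(GeneModel(name, chrom, start, end, strand, exonic))
    records.sort(key=lambda r: (r.chrom, r.start, r.end))
    return records


def genes_to_frame(genes: Sequence[GeneModel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
            "exonic_length": [g.exonic_length for g in genes],
        }
    )


def write_genes_bed(genes_df: pd.DataFrame, path: Union[str, Path]) -> None:
    out = genes_df[["chrom", "start", "end", "gene_id", "exonic_length", "strand"]]
    out = out.sort_values(["chrom", "start", "end"], kind="mergesort")
    out.to_csv(path, sep="\t", index=False, header=False)


def write_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a result table as TSV with a deterministic column order."""
    df.to_csv(path, sep="\t", index=False)
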
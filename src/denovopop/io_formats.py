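"""Readers and writers for the standard formats the pipeline touches.

All genomic coordinates are held internally as 0-based half-open intervals;
conversion to/from the 1-based conventions of VCF and GFF3 happens only in
this module.  Sequences are uppercased DNA over {A, C, G, T, N} (plus ``-``
inside alignments); RNA input is mapped to DNA (U -> T) at ingestion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pyranges as pr
import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "SequenceRecord",
    "VariantRecord",
    "AlleleState",
    "GenotypeMatrix",
    "GenomicInterval",
    "FormatError",
    "read_sequences",
    "write_sequences",
    "read_variants",
    "write_variants",
    "read_intervals",
    "write_intervals",
    "read_table",
]


class FormatError(ValueError):
    """A file violated the expectations of its declared format."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence; gaps ('-') only appear in alignment members."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")

    def __len__(self) -> int:
        return len(self.seq)

    def ungapped(self) -> str:
        return self.seq.replace("-", "")


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant; ``pos`` is 1-based as in VCF."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"variant position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise FormatError("variant ref and alt must be non-empty")
        if self.ref == self.alt:
            raise FormatError(f"ref equals alt at {self.chrom}:{self.pos}")

    @property
    def pos0(self) -> int:
        """0-based start of the reference span."""
        return self.pos - 1


class AlleleState(IntEnum):
    REF = 0
    ALT = 1
    HET = 2
    MISSING = 3


@dataclass
class GenotypeMatrix:
    """Per-(accession, variant) allele states for a set of biallelic variants."""

    accessions: list[str]
    variants: list[VariantRecord]
    calls: np.ndarray  # shape (n_accessions, n_variants), dtype int8

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.accessions), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.accessions)} accessions x {len(self.variants)} variants"
            )

    def call(self, accession: str, variant_index: int) -> AlleleState:
        return AlleleState(self.calls[self.accessions.index(accession), variant_index])


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval."""

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in {"+", "-", "."}:
            raise FormatError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


# ---------------------------------------------------------------------------
# FASTA


def read_sequences(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into uppercased :class:`SequenceRecord` objects.

    U is mapped to T.  Duplicate ids and empty files raise
    :class:`FormatError`.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_sequences(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF


def _map_gt(alleles: tuple, alt_index: int) -> AlleleState:
    # ``alleles`` is pysam's per-sample GT tuple (ints or None); ``alt_index``
    # is the 1-based ALT number this biallelic record was split from.
    if any(a is None for a in alleles) or len(alleles) == 0:
        return AlleleState.MISSING
    hits = sum(1 for a in alleles if a == alt_index)
    if hits == len(alleles):
        return AlleleState.ALT
    if hits == 0:
        # calls for *other* alt alleles count as non-carrier here; a genotype
        # that is entirely other-alt is not REF but is REF w.r.t. this allele
        return AlleleState.REF
    return AlleleState.HET


def read_variants(path: str | Path) -> GenotypeMatrix:
    """Read a VCF (v4.x, GT required) into a :class:`GenotypeMatrix`.

    Multi-allelic records are split into biallelic variants; spanning-deletion
    star alleles are dropped with a warning.  Diploid genotypes map as
    0/0 -> REF, 1/1 -> ALT, 0/1 or 1/0 -> HET, ./. -> MISSING; phasing is
    ignored.
    """
    vcf = pysam.VariantFile(str(path))
    if "GT" not in vcf.header.formats:
        raise FormatError(f"VCF {path} lacks a GT FORMAT definition")
    accessions = list(vcf.header.samples)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if rec.alts is None:
            continue
        for ai, alt in enumerate(rec.alts, start=1):
            if alt == "*":
                logger.warning(
                    "dropping star allele at %s:%d", rec.chrom, rec.pos
                )
                continue
            variants.append(
                VariantRecord(rec.chrom, rec.pos, rec.ref, alt, rec.id)
            )
            col = np.empty(len(accessions), dtype=np.int8)
            for si, sample in enumerate(rec.samples.values()):
                if "GT" not in sample:
                    raise FormatError(
                        f"missing GT for sample at {rec.chrom}:{rec.pos}"
                    )
                col[si] = _map_gt(sample["GT"], ai)
            columns.append(col)
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(accessions), 0), dtype=np.int8)
    )
    return GenotypeMatrix(accessions, variants, calls)


_GT_STRINGS = {
    AlleleState.REF: "0/0",
    AlleleState.ALT: "1/1",
    AlleleState.HET: "0/1",
    AlleleState.MISSING: "./.",
}


def write_variants(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a genotype matrix as an uncompressed VCF v4.2 file."""
    chroms = sorted({v.chrom for v in matrix.variants})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=denovopop\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.accessions)
            + "\n"
        )
        order = sorted(
            range(len(matrix.variants)),
            key=lambda i: (matrix.variants[i].chrom, matrix.variants[i].pos),
        )
        for i in order:
            v = matrix.variants[i]
            gts = "\t".join(
                _GT_STRINGS[AlleleState(s)] for s in matrix.calls[:, i]
            )
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id or '.'}\t{v.ref}\t{v.alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Intervals (BED / GFF3)


def read_intervals(path: str | Path, dialect: str) -> list[GenomicInterval]:
    """Read genomic intervals from BED or GFF3 into the internal convention.

    ``dialect`` must be ``"bed"`` (0-based half-open, taken as-is) or
    ``"gff3"`` (1-based closed, converted).  For GFF3 only CDS features are
    returned, grouped per gene id (``Parent`` or ``ID`` attribute) and sorted
    by coordinate.
    """
    if dialect == "bed":
        df = pr.read_bed(str(path)).df
        out = []
        for row in df.itertuples():
            out.append(
                GenomicInterval(
                    str(row.Chromosome),
                    int(row.Start),
                    int(row.End),
                    str(getattr(row, "Name", ".")),
                    str(getattr(row, "Strand", ".")),
                )
            )
        return out
    if dialect == "gff3":
        df = pr.read_gff3(str(path)).df  # pyranges converts to 0-based half-open
        df = df[df.Feature == "CDS"]
        out = []
        for row in df.itertuples():
            name = getattr(row, "Parent", None) or getattr(row, "ID", ".")
            out.append(
                GenomicInterval(
                    str(row.Chromosome),
                    int(row.Start),
                    int(row.End),
                    str(name),
                    str(getattr(row, "Strand", ".")),
                )
            )
        out.sort(key=lambda iv: (iv.name, iv.chrom, iv.start))
        return out
    raise ValueError(f"unknown interval dialect {dialect!r} (use 'bed' or 'gff3')")


def write_intervals(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Tables


def read_table(path: str | Path, required: Sequence[str] = ()) -> pd.DataFrame:
    """Read a TSV with header; check that ``required`` columns are present.

    Extra columns are preserved; row order is preserved; a header-only file
    yields a zero-row frame.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(
            f"table {path} is missing required column(s): {', '.join(missing)}"
        )
    return df
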
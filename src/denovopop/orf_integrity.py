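"""ORF integrity: apply an accession's variants to the reference CDS and
classify the resulting open reading frame.

A gene is called *present* in an accession when its CDS carries no
loss-of-function change: the start codon is intact, no premature stop codon
appears before the reference terminal codon, and the terminal stop codon is
still reached.  Frameshifting indels are judged by their translated
consequence, so they surface as PREMATURE_STOP or STOP_LOST rather than as a
category of their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from Bio.Seq import Seq

from .io_formats import (
    AlleleState,
    GenomicInterval,
    GenotypeMatrix,
    SequenceRecord,
    VariantRecord,
)

__all__ = [
    "GeneModel",
    "OrfStatus",
    "ORFCall",
    "extract_cds",
    "apply_variants",
    "classify_orf",
    "call_presence",
    "genomic_to_cds_variants",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODON = "ATG"


@dataclass
class GeneModel:
    """A single-transcript gene model: ordered CDS intervals on one strand."""

    gene_id: str
    chrom: str
    strand: str
    cds_intervals: list[GenomicInterval]
    frame_warning: bool = False

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        ivs = sorted(self.cds_intervals, key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if a.end > b.start:
                raise ValueError(f"gene {self.gene_id}: overlapping CDS intervals")
        self.cds_intervals = ivs

    @property
    def cds_length(self) -> int:
        return sum(len(iv) for iv in self.cds_intervals)

    @property
    def reference_protein_len(self) -> int:
        """Reference protein length in amino acids (terminal stop excluded)."""
        return self.cds_length // 3 - 1


class OrfStatus(Enum):
    FUNCTIONAL = "FUNCTIONAL"
    START_LOST = "START_LOST"
    PREMATURE_STOP = "PREMATURE_STOP"
    STOP_LOST = "STOP_LOST"
    UNRESOLVED = "UNRESOLVED"


@dataclass
class ORFCall:
    accession: str
    gene_id: str
    status: OrfStatus
    present: bool
    events: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.present != (self.status is OrfStatus.FUNCTIONAL):
            raise ValueError("present must be true iff status is FUNCTIONAL")


def extract_cds(genome: dict[str, SequenceRecord] | list[SequenceRecord], model: GeneModel) -> str:
    """Concatenate the model's CDS intervals in coding orientation.

    Minus-strand genes are reverse-complemented.  An out-of-bounds interval
    raises; a reference CDS that does not start with ATG, end with a stop
    codon, or have length divisible by 3 sets ``model.frame_warning``.
    """
    if isinstance(genome, list):
        genome = {rec.id: rec for rec in genome}
    if model.chrom not in genome:
        raise KeyError(f"chromosome {model.chrom!r} not in genome")
    chrom_seq = genome[model.chrom].seq
    parts = []
    for iv in model.cds_intervals:
        if iv.end > len(chrom_seq):
            raise ValueError(
                f"gene {model.gene_id}: interval {iv.start}-{iv.end} exceeds "
                f"chromosome length {len(chrom_seq)}"
            )
        parts.append(chrom_seq[iv.start : iv.end])
    cds = "".join(parts)
    if model.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    if (
        len(cds) % 3 != 0
        or not cds.startswith(START_CODON)
        or cds[-3:] not in STOP_CODONS
    ):
        model.frame_warning = True
    return cds


def apply_variants(cds: str, variants: list[tuple[int, str, str]]) -> str:
    """Apply (cds_pos, ref, alt) edits to a CDS string.

    Each edit replaces the half-open slice ``[pos, pos + len(ref))`` with
    ``alt`` (VCF-style left-anchored indels, already normalised to CDS
    coordinates).  Edits must match the reference and must not overlap; they
    are applied in descending coordinate order so earlier edits never shift
    later coordinates.
    """
    spans = sorted(((pos, pos + len(ref)) for pos, ref, _ in variants))
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if e1 > s2:
            raise ValueError(f"overlapping variants at CDS positions {s1} and {s2}")
    seq = cds
    for pos, ref, alt in sorted(variants, key=lambda v: -v[0]):
        if pos < 0 or pos + len(ref) > len(seq):
            raise ValueError(f"variant at CDS position {pos} out of bounds")
        if seq[pos : pos + len(ref)] != ref:
            raise ValueError(
                f"reference mismatch at CDS position {pos}: expected "
                f"{ref!r}, found {seq[pos:pos + len(ref)]!r}"
            )
        seq = seq[:pos] + alt + seq[pos + len(ref) :]
    return seq


def classify_orf(seq: str, reference_protein_len: int) -> OrfStatus:
    """Classify an edited CDS against the reference reading frame.

    START_LOST if the sequence does not begin with ATG; otherwise the first
    in-frame stop codon decides: none reached -> STOP_LOST; reached strictly
    before the reference terminal codon position -> PREMATURE_STOP (any
    truncation counts, however close to the terminus); else FUNCTIONAL.
    """
    if not seq:
        raise ValueError("cannot classify an empty sequence")
    if not seq.startswith(START_CODON):
        return OrfStatus.START_LOST
    for codon_index in range(len(seq) // 3):
        codon = seq[3 * codon_index : 3 * codon_index + 3]
        if codon in STOP_CODONS:
            if codon_index < reference_protein_len:
                return OrfStatus.PREMATURE_STOP
            return OrfStatus.FUNCTIONAL
    return OrfStatus.STOP_LOST


def genomic_to_cds_variants(
    model: GeneModel, variants: list[VariantRecord]
) -> list[tuple[int, str, str, int]]:
    """Map genomic variants to CDS coordinates in coding orientation.

    Returns (cds_pos, ref, alt, original_index) tuples.  On the minus strand
    ref/alt are reverse-complemented and the position re-anchored to the
    coding-strand start of the edited span.  Variants whose reference span is
    not fully contained in the CDS footprint are rejected.
    """
    offsets: list[tuple[GenomicInterval, int]] = []
    acc = 0
    for iv in model.cds_intervals:
        offsets.append((iv, acc))
        acc += len(iv)
    total = acc

    def to_plus_cds(gpos0: int) -> int | None:
        for iv, off in offsets:
            if iv.start <= gpos0 < iv.end:
                return off + (gpos0 - iv.start)
        return None

    out = []
    for idx, v in enumerate(variants):
        if v.chrom != model.chrom:
            raise ValueError(f"variant {v.chrom}:{v.pos} not on gene chromosome")
        start = to_plus_cds(v.pos0)
        end = to_plus_cds(v.pos0 + len(v.ref) - 1)
        if start is None or end is None or end - start != len(v.ref) - 1:
            raise ValueError(
                f"variant {v.chrom}:{v.pos} not fully inside the CDS of "
                f"{model.gene_id}"
            )
        if model.strand == "+":
            out.append((start, v.ref, v.alt, idx))
        else:
            ref_rc = str(Seq(v.ref).reverse_complement())
            alt_rc = str(Seq(v.alt).reverse_complement())
            out.append((total - 1 - end, ref_rc, alt_rc, idx))
    return out


def call_presence(
    gene: GeneModel,
    genotypes: GenotypeMatrix,
    reference_cds: str,
    policy: str = "strict",
) -> list[ORFCall]:
    """One ORF presence call per accession.

    ``strict`` marks any accession with a HET or MISSING genotype at one of
    the gene's variant sites UNRESOLVED (selfing species: heterozygous calls
    are most likely errors).  ``any-functional`` instead skips HET/MISSING
    sites, i.e. calls the accession by its REF-allele haplotype.
    """
    if policy not in {"strict", "any-functional"}:
        raise ValueError(f"unknown policy {policy!r}")
    ref_len = len(reference_cds) // 3 - 1
    cds_variants = genomic_to_cds_variants(gene, genotypes.variants)
    calls = []
    for ai, accession in enumerate(genotypes.accessions):
        states = genotypes.calls[ai]
        unresolved = False
        edits: list[tuple[int, str, str]] = []
        events: list[str] = []
        for pos, ref, alt, idx in cds_variants:
            state = AlleleState(states[idx])
            if state is AlleleState.ALT:
                edits.append((pos, ref, alt))
            elif state in (AlleleState.HET, AlleleState.MISSING):
                if policy == "strict":
                    unresolved = True
        if unresolved:
            calls.append(
                ORFCall(accession, gene.gene_id, OrfStatus.UNRESOLVED, False)
            )
            continue
        seq = apply_variants(reference_cds, edits)
        status = classify_orf(seq, ref_len)
        if status is not OrfStatus.FUNCTIONAL:
            for pos, ref, alt in sorted(edits):
                events.append(f"cds:{pos}:{ref}>{alt}")
        calls.append(
            ORFCall(
                accession,
                gene.gene_id,
                status,
                status is OrfStatus.FUNCTIONAL,
                events,
            )
        )
    return calls
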
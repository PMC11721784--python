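"""Codon-aware evolutionary history of an ORF from an outgroup-rooted
ortholog alignment.

All sequences are assumed aligned to the reference genome and translated in
the reference reading frame; indels in individual sequences therefore do not
shift codon indexing, which always follows the reference columns.  The
module provides a column-wise Fitch parsimony reconstruction of the ingroup
ancestor (an externally produced ancestor can be supplied verbatim instead),
per-branch annotation of substitutions and indels, a target-site-duplication
motif scan for the flanks, and the stringency filter for tabular homology
hits.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Phylo
from Bio.Seq import Seq

from .io_formats import FormatError, SequenceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "OrthologAlignment",
    "EventKind",
    "BranchEvent",
    "TSDHit",
    "HomologyHit",
    "reconstruct_ancestor_parsimony",
    "annotate_branch_events",
    "scan_tsd",
    "filter_homology_hits",
    "read_homology_hits",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODON = "ATG"


@dataclass
class OrthologAlignment:
    """Equal-length gapped records with a designated reference sequence.

    ``frame_offset`` is the alignment column holding the reference's first
    CDS base; the reference must contain a whole number of codons after gap
    removal from that column on.
    """

    records: list[SequenceRecord]
    reference_id: str
    frame_offset: int = 0

    def __post_init__(self) -> None:
        lengths = {len(r.seq) for r in self.records}
        if len(lengths) != 1:
            raise FormatError("alignment records differ in length")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate ids in alignment")
        if self.reference_id not in ids:
            raise FormatError(f"reference {self.reference_id!r} not in alignment")
        ref = self.get(self.reference_id)
        n_ref_bases = sum(
            1 for b in ref.seq[self.frame_offset :] if b != "-"
        )
        if n_ref_bases % 3 != 0:
            raise FormatError(
                "reference has a fractional number of codons after gap removal"
            )

    @property
    def length(self) -> int:
        return len(self.records[0].seq)

    def get(self, record_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == record_id:
                return r
        raise KeyError(record_id)

    def reference_codon_columns(self) -> list[list[int]]:
        """Alignment columns of each reference codon, in frame order."""
        ref = self.get(self.reference_id)
        cols = [
            i
            for i in range(self.frame_offset, self.length)
            if ref.seq[i] != "-"
        ]
        return [cols[i : i + 3] for i in range(0, len(cols), 3)]


# ---------------------------------------------------------------------------
# Parsimony ancestor


def _fitch_sets(clade, states: Mapping[str, str]) -> frozenset[str]:
    if clade.is_terminal():
        return frozenset({states[clade.name]})
    child_sets = [_fitch_sets(c, states) for c in clade.clades]
    inter = frozenset.intersection(*child_sets)
    if inter:
        return inter
    return frozenset.union(*child_sets)


def reconstruct_ancestor_parsimony(
    aln: OrthologAlignment, tree_newick: str, outgroup: str
) -> SequenceRecord:
    """Infer the ingroup ancestral sequence by column-wise Fitch parsimony.

    The tree is rooted with ``outgroup``; the Fitch up-pass runs over the
    ingroup subtree with the gap character as a fifth state.  Ambiguous
    columns are resolved by the outgroup state when it is a most-parsimonious
    choice, then by the reference state, then lexicographically (the last
    case cannot arise on quartets).
    """
    tree = Phylo.read(io.StringIO(tree_newick), "newick")
    leaves = [t.name for t in tree.get_terminals()]
    if len(leaves) < 3:
        raise ValueError("tree must have at least 3 leaves")
    if outgroup not in leaves:
        raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")
    aln_ids = {r.id for r in aln.records}
    missing = [name for name in leaves if name not in aln_ids]
    if missing:
        raise ValueError(f"tree leaves missing from alignment: {missing}")
    tree.root_with_outgroup(outgroup)
    ingroup_clades = [
        c for c in tree.root.clades if outgroup not in
        {t.name for t in c.get_terminals()}
    ]
    seqs = {r.id: r.seq for r in aln.records}
    out_seq = seqs[outgroup]
    ref_seq = seqs[aln.reference_id]
    ancestor = []
    for col in range(aln.length):
        states = {name: seqs[name][col] for name in leaves}
        col_sets = [_fitch_sets(c, states) for c in ingroup_clades]
        inter = frozenset.intersection(*col_sets)
        root_set = inter if inter else frozenset.union(*col_sets)
        if len(root_set) == 1:
            (state,) = root_set
        elif out_seq[col] in root_set:
            state = out_seq[col]
        elif ref_seq[col] in root_set:
            state = ref_seq[col]
        else:
            state = min(root_set)
        ancestor.append(state)
    return SequenceRecord("ancestor", "".join(ancestor))


# ---------------------------------------------------------------------------
# Branch events


class EventKind(Enum):
    SYN = "SYN"
    NONSYN = "NONSYN"
    STOP_GAIN = "STOP_GAIN"
    STOP_LOSS = "STOP_LOSS"
    START_LOST = "START_LOST"
    INS = "INS"
    DEL = "DEL"
    UNFRAMED = "UNFRAMED"  # substitution outside the reference codons


@dataclass
class BranchEvent:
    branch: tuple[str, str]
    kind: EventKind
    codon_index: int | None
    column_span: tuple[int, int]  # half-open alignment columns
    detail: str
    multi_hit: bool = False


def _classify_sub(
    parent_codon: str, child_codon: str, codon_index: int
) -> EventKind:
    if "-" in parent_codon or "-" in child_codon:
        return EventKind.UNFRAMED
    parent_stop = parent_codon in STOP_CODONS
    child_stop = child_codon in STOP_CODONS
    if parent_stop and not child_stop:
        return EventKind.STOP_LOSS
    if child_stop and not parent_stop:
        return EventKind.STOP_GAIN
    if codon_index == 0 and parent_codon == START_CODON and child_codon != START_CODON:
        return EventKind.START_LOST
    if parent_stop and child_stop:
        return EventKind.SYN  # stop-to-stop exchange preserves termination
    aa_parent = str(Seq(parent_codon).translate())
    aa_child = str(Seq(child_codon).translate())
    return EventKind.SYN if aa_parent == aa_child else EventKind.NONSYN


def annotate_branch_events(
    parent: SequenceRecord,
    child: SequenceRecord,
    aln: OrthologAlignment,
    multi_hit: str = "per-site",
) -> list[BranchEvent]:
    """Annotate the changes along one tree branch (parent -> child).

    Maximal runs of gap-vs-base columns are emitted as single INS/DEL events.
    Each substituted column is classified inside its reference-frame codon by
    substituting that site alone while holding the other two positions at the
    parent state; stop gains/losses take precedence over SYN/NONSYN (and over
    START_LOST).  Codons hit at more than one site are flagged ``multi_hit``;
    with ``multi_hit="per-codon"`` such a codon is instead emitted as one
    event classified by the joint parent-codon -> child-codon change.
    """
    if multi_hit not in {"per-site", "per-codon"}:
        raise ValueError(f"unknown multi_hit mode {multi_hit!r}")
    if len(parent.seq) != aln.length or len(child.seq) != aln.length:
        raise ValueError("parent/child do not match the alignment length")
    branch = (parent.id, child.id)
    codon_cols = aln.reference_codon_columns()
    codon_of_col: dict[int, int] = {}
    for ci, cols in enumerate(codon_cols):
        for c in cols:
            codon_of_col[c] = ci

    events: list[BranchEvent] = []

    # indel runs
    run_kind: EventKind | None = None
    run_start = 0
    for col in range(aln.length + 1):
        if col < aln.length:
            p, c = parent.seq[col], child.seq[col]
            if p == "-" and c != "-":
                kind = EventKind.INS
            elif p != "-" and c == "-":
                kind = EventKind.DEL
            else:
                kind = None
        else:
            kind = None
        if kind != run_kind:
            if run_kind is not None:
                span = (run_start, col)
                first_codon = next(
                    (codon_of_col[x] for x in range(*span) if x in codon_of_col),
                    None,
                )
                seq = (child if run_kind is EventKind.INS else parent).seq
                events.append(
                    BranchEvent(
                        branch,
                        run_kind,
                        first_codon,
                        span,
                        f"{run_kind.value.lower()}:{seq[span[0]:span[1]]}",
                    )
                )
            run_kind = kind
            run_start = col

    # substitutions
    subs = [
        col
        for col in range(aln.length)
        if parent.seq[col] != child.seq[col]
        and parent.seq[col] != "-"
        and child.seq[col] != "-"
    ]
    subs_by_codon: dict[int | None, list[int]] = {}
    for col in subs:
        subs_by_codon.setdefault(codon_of_col.get(col), []).append(col)

    for ci, cols in sorted(
        subs_by_codon.items(), key=lambda kv: (kv[0] is None, kv[0])
    ):
        if ci is None:
            for col in cols:
                events.append(
                    BranchEvent(
                        branch,
                        EventKind.UNFRAMED,
                        None,
                        (col, col + 1),
                        f"{parent.seq[col]}>{child.seq[col]}",
                    )
                )
            continue
        codon_columns = codon_cols[ci]
        parent_codon = "".join(parent.seq[x] for x in codon_columns)
        hit = len(cols) > 1
        if hit and multi_hit == "per-codon":
            child_codon = "".join(
                child.seq[x] if x in cols else parent.seq[x]
                for x in codon_columns
            )
            kind = _classify_sub(parent_codon, child_codon, ci)
            events.append(
                BranchEvent(
                    branch,
                    kind,
                    ci,
                    (min(cols), max(cols) + 1),
                    f"{parent_codon}>{child_codon}",
                    multi_hit=True,
                )
            )
            continue
        for col in cols:
            child_codon = "".join(
                child.seq[x] if x == col else parent.seq[x]
                for x in codon_columns
            )
            kind = _classify_sub(parent_codon, child_codon, ci)
            events.append(
                BranchEvent(
                    branch,
                    kind,
                    ci,
                    (col, col + 1),
                    f"{parent_codon}>{child_codon}",
                    multi_hit=hit,
                )
            )
    events.sort(key=lambda e: e.column_span)
    return events


def count_events(events: Iterable[BranchEvent]) -> dict[str, int]:
    """Tally events by kind (convenience for figure-style summaries)."""
    out = {k.value: 0 for k in EventKind}
    for e in events:
        out[e.kind.value] += 1
    return out


# ---------------------------------------------------------------------------
# TSD scan


@dataclass(frozen=True)
class TSDHit:
    start: int  # 0-based in the flank
    end: int  # half-open
    distance_upstream: int  # 1-based bp from motif 3' end to the base before ATG
    mismatches: int


def scan_tsd(
    flank: SequenceRecord,
    motif: str,
    start_codon_pos: int,
    max_mismatches: int = 0,
) -> list[TSDHit]:
    """Find target-site-duplication motif remnants in a flanking sequence.

    Distances are 1-based bp upstream of the first base of the start codon:
    a motif whose 3' end immediately abuts the ATG is 1 bp upstream.  Hits
    are returned 5'->3'; only occurrences wholly 5' of the start codon are
    reported.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if not 0 <= start_codon_pos <= len(flank.seq):
        raise ValueError("start_codon_pos outside the flank")
    motif = motif.upper()
    m = len(motif)
    hits = []
    for i in range(0, start_codon_pos - m + 1):
        window = flank.seq[i : i + m]
        mm = sum(1 for a, b in zip(window, motif) if a != b)
        if mm <= max_mismatches:
            hits.append(TSDHit(i, i + m, start_codon_pos - i - m + 1, mm))
    return hits


# ---------------------------------------------------------------------------
# Homology-hit filtering


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    pct_identity: float
    align_len: int
    evalue: float
    qcov: float


def read_homology_hits(
    path: str, query_lengths: Mapping[str, int] | None = None
) -> list[HomologyHit]:
    """Read a BLAST outfmt-6-like TSV (first 11 standard columns used).

    Query coverage is taken from a ``qcov`` column when present, else derived
    as 100 * align_len / query length from ``query_lengths``.
    """
    df = pd.read_csv(path, sep="\t")
    hits = []
    for row in df.itertuples(index=False):
        if "qcov" in df.columns:
            qcov = float(row.qcov)
        elif query_lengths is not None:
            qcov = 100.0 * int(row.align_len) / query_lengths[str(row.query_id)]
        else:
            raise FormatError("qcov column absent and no query lengths supplied")
        hits.append(
            HomologyHit(
                str(row.query_id),
                str(row.subject_id),
                float(row.pct_identity),
                int(row.align_len),
                float(row.evalue),
                qcov,
            )
        )
    return hits


def filter_homology_hits(
    hits: Iterable[HomologyHit],
    max_evalue: float = 1e-5,
    min_identity: float = 60.0,
    min_qcov: float = 70.0,
) -> list[HomologyHit]:
    """Stringency filter: E <= 1e-5, identity >= 60 %, query cover >= 70 %.

    All bounds inclusive.  Rows with negative or non-finite fields are
    rejected with a warning.
    """
    retained = []
    for h in hits:
        fields = (h.pct_identity, h.align_len, h.evalue, h.qcov)
        if any(not math.isfinite(x) or x < 0 for x in fields):
            logger.warning("rejecting malformed homology hit %s", h)
            continue
        if h.evalue <= max_evalue and h.pct_identity >= min_identity and h.qcov >= min_qcov:
            retained.append(h)
    return retained
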
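"""Synthetic inputs with known planted truth for every pipeline stage.

Each generator emulates one input class of the population analyses: genotype
matrices with loss-of-function variants planted at exact per-population
frequencies, haplotype matrices with a planted sweep LD signature, two-group
bioclimatic tables with a stated mean shift, and ortholog quartets with
planted substitution/indel/stop-codon events.  Planted counts are census
values (rounded, not sampled), so downstream recovery tests are exact.  A
single global seed fans out to per-scenario substreams by stable hashing of
the scenario name; the same (scenario, seed) always regenerates identical
data.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io_formats import (
    AlleleState,
    GenomicInterval,
    GenotypeMatrix,
    SequenceRecord,
    VariantRecord,
    write_sequences,
    write_variants,
)
from .orf_integrity import GeneModel
from .sweep_scan import HaplotypeMatrix

__all__ = [
    "substream",
    "CatalogBundle",
    "gen_catalog_variants",
    "SweepBundle",
    "gen_sweep_haplotypes",
    "EnvBundle",
    "gen_env",
    "QuartetBundle",
    "gen_ortholog_quartet",
]

STOPS = {"TAA", "TAG", "TGA"}
BASES = "ACGT"
SAFE_CODONS = [
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOPS
]
LOF_TYPES = ["premature_stop", "start_loss", "frameshift_del", "stop_loss"]


def substream(seed: int, scenario: str) -> np.random.Generator:
    """Independent, reproducible RNG substream for a named scenario."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(scenario.encode())])
    )


def _write_truth(truth: dict, out_dir: Path) -> Path:
    path = out_dir / "truth.json"
    path.write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# Catalog of genes with planted LoF variants


@dataclass
class CatalogBundle:
    genome: dict[str, SequenceRecord]
    models: list[GeneModel]
    genotypes: GenotypeMatrix
    pop_map: dict[str, str]
    truth: dict
    paths: dict[str, Path] = field(default_factory=dict)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    internal = rng.choice(SAFE_CODONS, size=n_codons - 2)
    return "ATG" + "".join(internal) + "TAA"


def _is_lof(seq: str, ref_protein_len: int) -> bool:
    # ground-truth LoF check by direct translation walk, independent of the
    # classifier under test
    if not seq.startswith("ATG"):
        return True
    for i in range(len(seq) // 3):
        if seq[3 * i : 3 * i + 3] in STOPS:
            return i < ref_protein_len
    return True  # no stop reached


def _plan_lof_edits(
    cds: str, stop_codon_idx: int, rng: np.random.Generator
) -> dict[str, tuple[int, str, str]]:
    """One CDS-space edit (pos, ref, alt) per LoF type for one gene.

    ``cds`` is the final reference CDS, which carries TAC at
    ``stop_codon_idx`` so a single third-position substitution creates TAA.
    The frameshift deletion site is verified (and shifted if necessary) so
    the shifted frame really truncates the protein.
    """
    n_codons = len(cds) // 3
    ref_protein_len = n_codons - 1
    edits: dict[str, tuple[int, str, str]] = {}
    # start loss: A of ATG -> C
    edits["start_loss"] = (0, "A", "C")
    # stop loss: first base of the terminal stop codon
    term = 3 * (n_codons - 1)
    edits["stop_loss"] = (term, cds[term], "C")
    # premature stop: TAC -> TAA at the planted codon
    edits["premature_stop"] = (3 * stop_codon_idx + 2, "C", "A")
    # frameshift: VCF-style anchored 1-bp deletion
    d = int(rng.integers(4, 3 * (n_codons - 2)))
    for shift in range(3 * n_codons):
        pos = 3 + (d - 3 + shift) % (3 * (n_codons - 2))
        edited = cds[:pos] + cds[pos + 1 :]
        if _is_lof(edited, ref_protein_len):
            edits["frameshift_del"] = (pos - 1, cds[pos - 1 : pos + 1], cds[pos - 1])
            break
    else:  # pragma: no cover - a frameshift that never truncates
        raise RuntimeError("could not place a truncating frameshift")
    return edits


def _edit_to_genomic(
    model: GeneModel, cds_pos: int, ref: str, alt: str
) -> VariantRecord:
    """Map a CDS-space edit back to a genomic VariantRecord (1-based)."""
    iv = model.cds_intervals[0]  # generator emits single-interval genes
    if model.strand == "+":
        g0 = iv.start + cds_pos
        return VariantRecord(model.chrom, g0 + 1, ref, alt)
    g_end = iv.end - cds_pos  # exclusive genomic end of the edited span
    g0 = g_end - len(ref)
    ref_rc = str(Seq(ref).reverse_complement())
    alt_rc = str(Seq(alt).reverse_complement())
    return VariantRecord(model.chrom, g0 + 1, ref_rc, alt_rc)


def gen_catalog_variants(
    populations: Mapping[str, int],
    n_genes: int,
    lof_freq,
    seed: int,
    n_codons: int = 40,
    out_dir: str | Path | None = None,
) -> CatalogBundle:
    """Reference genome, gene models, genotypes and planted LoF truth.

    ``lof_freq`` is the absence (loss-of-function) frequency per gene and
    population: a scalar, an (n_genes, n_populations) array, or a nested
    mapping gene-id -> population -> frequency in [0, 1].  Per population the
    number of absent accessions is ``round(freq * size)`` — exact census
    counts, not binomial draws — and each absent accession carries exactly
    one planted LoF variant of a uniformly drawn type (premature-stop SNP,
    start-loss SNP, 1-bp frameshift deletion, or stop-loss SNP).
    """
    rng = substream(seed, "catalog")
    pop_names = list(populations)
    gene_ids = [f"gene{g + 1}" for g in range(n_genes)]
    freq = np.zeros((n_genes, len(pop_names)))
    if isinstance(lof_freq, Mapping):
        for gi, gid in enumerate(gene_ids):
            for pi, pop in enumerate(pop_names):
                freq[gi, pi] = lof_freq.get(gid, {}).get(pop, 0.0)
    else:
        freq[:, :] = np.asarray(lof_freq, dtype=float)
    if freq.min() < 0 or freq.max() > 1:
        raise ValueError("lof_freq values must lie in [0, 1]")

    accessions = [
        f"{pop}_{i + 1:04d}" for pop in pop_names for i in range(populations[pop])
    ]
    pop_map = {acc: acc.rsplit("_", 1)[0] for acc in accessions}

    spacer = 100
    chrom = "1"
    genome_parts: list[str] = []
    cursor = 0
    models: list[GeneModel] = []
    cds_by_gene: dict[str, str] = {}
    edits_by_gene: dict[str, dict[str, tuple[int, str, str]]] = {}
    for gi, gid in enumerate(gene_ids):
        cds = _random_cds(rng, n_codons)
        # plant a TAC codon so a single substitution can create a premature TAA
        j = int(rng.integers(2, n_codons - 2))
        cds = cds[: 3 * j] + "TAC" + cds[3 * j + 3 :]
        edits = _plan_lof_edits(cds, j, rng)
        strand = "+" if gi % 2 == 0 else "-"
        pad = "".join(rng.choice(list(BASES), size=spacer))
        genome_parts.append(pad)
        cursor += spacer
        start = cursor
        gene_seq = cds if strand == "+" else str(Seq(cds).reverse_complement())
        genome_parts.append(gene_seq)
        cursor += len(cds)
        model = GeneModel(
            gid,
            chrom,
            strand,
            [GenomicInterval(chrom, start, start + len(cds), gid, strand)],
        )
        models.append(model)
        cds_by_gene[gid] = cds
        edits_by_gene[gid] = edits
    genome_parts.append("".join(rng.choice(list(BASES), size=spacer)))
    genome = {chrom: SequenceRecord(chrom, "".join(genome_parts))}

    variants: list[VariantRecord] = []
    var_index: dict[tuple[str, str], int] = {}
    for gid, model in zip(gene_ids, models):
        for lof_type in LOF_TYPES:
            pos, ref, alt = edits_by_gene[gid][lof_type]
            var_index[(gid, lof_type)] = len(variants)
            variants.append(_edit_to_genomic(model, pos, ref, alt))

    calls = np.full((len(accessions), len(variants)), AlleleState.REF, dtype=np.int8)
    truth_rows = []
    acc_offsets = {}
    off = 0
    for pop in pop_names:
        acc_offsets[pop] = off
        off += populations[pop]
    for gi, gid in enumerate(gene_ids):
        for pi, pop in enumerate(pop_names):
            size = populations[pop]
            n_absent = int(round(freq[gi, pi] * size))
            chosen = rng.choice(size, size=n_absent, replace=False)
            carriers = {}
            for a in sorted(int(x) for x in chosen):
                lof_type = LOF_TYPES[int(rng.integers(len(LOF_TYPES)))]
                acc = accessions[acc_offsets[pop] + a]
                calls[acc_offsets[pop] + a, var_index[(gid, lof_type)]] = AlleleState.ALT
                carriers[acc] = lof_type
            truth_rows.append(
                {
                    "gene_id": gid,
                    "population": pop,
                    "n_accessions": size,
                    "n_absent": n_absent,
                    "requested_lof_freq": float(freq[gi, pi]),
                    "realized_lof_freq": n_absent / size,
                    "presence_freq_pct": round(100.0 * (size - n_absent) / size, 10),
                    "carriers": carriers,
                }
            )
    genotypes = GenotypeMatrix(accessions, variants, calls)
    truth = {"scenario": "catalog", "seed": int(seed), "records": truth_rows}

    bundle = CatalogBundle(genome, models, genotypes, pop_map, truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_sequences(genome.values(), out / "reference.fasta")
        write_variants(genotypes, out / "variants.vcf")
        _write_gff3(models, out / "genes.gff3")
        pd.DataFrame(
            {"accession": accessions, "population": [pop_map[a] for a in accessions]}
        ).to_csv(out / "pops.tsv", sep="\t", index=False)
        bundle.paths = {
            "fasta": out / "reference.fasta",
            "vcf": out / "variants.vcf",
            "gff3": out / "genes.gff3",
            "pops": out / "pops.tsv",
            "truth": _write_truth(truth, out),
        }
    return bundle


def _write_gff3(models: Sequence[GeneModel], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            g_start = min(iv.start for iv in m.cds_intervals) + 1
            g_end = max(iv.end for iv in m.cds_intervals)
            fh.write(
                f"{m.chrom}\tdenovopop\tgene\t{g_start}\t{g_end}\t.\t{m.strand}\t."
                f"\tID={m.gene_id}\n"
            )
            for iv in m.cds_intervals:
                fh.write(
                    f"{m.chrom}\tdenovopop\tCDS\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{m.strand}\t0\tID=cds-{m.gene_id};Parent={m.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Sweep haplotypes


@dataclass
class SweepBundle:
    haplotypes: HaplotypeMatrix
    truth: dict
    paths: dict[str, Path] = field(default_factory=dict)


def gen_sweep_haplotypes(
    n_hap: int = 100,
    region_len: int = 200_000,
    n_sites: int = 800,
    sweep_center: int = 100_000,
    flank_width: int = 10_000,
    n_haplogroups: int = 2,
    sweep: bool = True,
    seed: int = 0,
) -> SweepBundle:
    """Haplotype matrix with (optionally) a planted sweep LD signature.

    Background sites are independent Bernoulli columns with per-site allele
    frequency uniform on [0.1, 0.5] (expected r-squared near 0).  Inside the
    sweep, each haplotype is independently assigned one of ``n_haplogroups``
    block patterns for the left flank and, independently, one for the right
    flank, giving within-flank r-squared of 1 and cross-flank r-squared near
    0 — the configuration that maximises omega at the centre.  Monomorphic
    columns are removed before returning, as at ingestion.
    """
    rng = substream(seed, "sweep")
    if sweep and not (0 < sweep_center - flank_width and sweep_center + flank_width < region_len):
        raise ValueError("sweep_center +/- flank_width must lie inside the region")
    positions = np.sort(
        rng.choice(np.arange(1, region_len), size=n_sites, replace=False)
    )
    maf = rng.uniform(0.1, 0.5, size=n_sites)
    hap = (rng.random((n_hap, n_sites)) < maf).astype(np.int8)
    truth = {
        "scenario": "sweep",
        "seed": int(seed),
        "sweep": bool(sweep),
        "sweep_center": int(sweep_center),
        "flank_width": int(flank_width),
        "n_haplogroups": int(n_haplogroups),
    }
    if sweep:
        left = np.flatnonzero(
            (positions >= sweep_center - flank_width) & (positions <= sweep_center)
        )
        right = np.flatnonzero(
            (positions > sweep_center) & (positions <= sweep_center + flank_width)
        )
        if len(left) < 2 or len(right) < 2:
            raise ValueError("fewer than 2 sites per sweep flank")
        for flank_sites in (left, right):
            groups = rng.integers(0, n_haplogroups, size=n_hap)
            pattern = rng.integers(0, 2, size=(n_haplogroups, len(flank_sites)))
            hap[:, flank_sites] = pattern[groups]
    matrix = HaplotypeMatrix(
        "1", positions, hap, region_start=0, region_end=region_len
    ).drop_monomorphic()
    return SweepBundle(matrix, truth)


# ---------------------------------------------------------------------------
# Environmental tables


@dataclass
class EnvBundle:
    env: pd.DataFrame
    present_ids: list[str]
    absent_ids: list[str]
    truth: dict
    paths: dict[str, Path] = field(default_factory=dict)


def gen_env(
    n_present: int,
    n_absent: int,
    effect: float,
    sd: float = 1.0,
    focal: str = "bio17",
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> EnvBundle:
    """Accession x bio1..bio19 table with a mean shift on one focal factor.

    Every factor is Normal(0, sd), independent across factors and
    accessions; the focal factor in the absent group is shifted by
    ``+effect``.  ``n_absent`` must be positive and ``sd`` strictly positive.
    """
    if n_absent < 1:
        raise ValueError("n_absent must be >= 1")
    if sd <= 0:
        raise ValueError("sd must be > 0")
    rng = substream(seed, "env")
    n = n_present + n_absent
    ids = [f"acc{i + 1:04d}" for i in range(n)]
    present_ids, absent_ids = ids[:n_present], ids[n_present:]
    factors = [f"bio{i}" for i in range(1, 20)]
    if focal not in factors:
        raise ValueError(f"focal factor {focal!r} is not one of bio1..bio19")
    data = {"accession": ids}
    for f in factors:
        col = rng.normal(0.0, sd, size=n)
        if f == focal:
            col[n_present:] += effect
        data[f] = col
    env = pd.DataFrame(data)
    truth = {
        "scenario": "env",
        "seed": int(seed),
        "focal": focal,
        "effect": float(effect),
        "sd": float(sd),
        "n_present": n_present,
        "n_absent": n_absent,
    }
    bundle = EnvBundle(env, present_ids, absent_ids, truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        env.to_csv(out / "env.tsv", sep="\t", index=False)
        (out / "present.txt").write_text("\n".join(present_ids) + "\n")
        (out / "absent.txt").write_text("\n".join(absent_ids) + "\n")
        bundle.paths = {
            "env": out / "env.tsv",
            "present": out / "present.txt",
            "absent": out / "absent.txt",
            "truth": _write_truth(truth, out),
        }
    return bundle


# ---------------------------------------------------------------------------
# Ortholog quartets


@dataclass
class QuartetBundle:
    alignment_records: list[SequenceRecord]  # outgroup, ancestor, ingroup1, ingroup2
    tree_newick: str
    reference_id: str
    outgroup_id: str
    truth: dict
    paths: dict[str, Path] = field(default_factory=dict)


_QUARTET_NODES = ["outgroup", "ancestor", "ingroup1", "ingroup2"]
_BRANCHES = {
    "outgroup->ancestor": {"ancestor", "ingroup1", "ingroup2"},
    "ancestor->ingroup1": {"ingroup1"},
    "ancestor->ingroup2": {"ingroup2"},
}
_SUB_EVENTS = {
    # kind -> (parent codon, child codon)
    "SYN": ("AAA", "AAG"),
    "NONSYN": ("AAA", "GAA"),
    "STOP_GAIN": ("TAC", "TAA"),
    "STOP_LOSS": ("TGA", "TGG"),
    "START_LOST": ("ATG", "ACG"),
}


def gen_ortholog_quartet(
    n_codons: int = 72,
    events: Mapping[str, Mapping[str, int]] | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> QuartetBundle:
    """Aligned quartet (outgroup, ancestor, two ingroup leaves) with planted
    branch events and exact truth.

    ``events`` maps a branch name (``outgroup->ancestor``,
    ``ancestor->ingroup1``, ``ancestor->ingroup2``) to per-kind counts over
    SYN / NONSYN / STOP_GAIN / STOP_LOSS / START_LOST / INS / DEL.  Every
    substitution occupies its own codon and indel blocks are codon-aligned
    and non-overlapping, so no codon is multi-hit and the annotator can
    recover the planted counts exactly.  The reference (Col-0-like) sequence
    is ``ingroup1``; the tree roots on ``outgroup``.
    """
    rng = substream(seed, "quartet")
    events = {b: dict(kinds) for b, kinds in (events or {}).items()}
    for b in events:
        if b not in _BRANCHES:
            raise ValueError(f"unknown branch {b!r}")
        for k in events[b]:
            if k not in set(_SUB_EVENTS) | {"INS", "DEL"}:
                raise ValueError(f"unknown event kind {k!r}")

    root_codons = ["ATG"] + [
        str(rng.choice(SAFE_CODONS)) for _ in range(n_codons - 2)
    ] + ["TAA"]

    # reserve distinct internal codon slots for substitutions and deletions
    n_sub = sum(
        c for b in events for k, c in events[b].items() if k in _SUB_EVENTS and k != "START_LOST"
    )
    n_del = sum(c for b in events for k, c in events[b].items() if k == "DEL")
    n_start = sum(c for b in events for k, c in events[b].items() if k == "START_LOST")
    if n_start > 1:
        raise ValueError("at most one START_LOST event can be planted")
    if n_sub + n_del > n_codons - 2:
        raise ValueError("too many events for the requested number of codons")
    internal = [int(x) for x in rng.permutation(np.arange(1, n_codons - 1))]

    # per-root-codon substitution plan: codon index -> (branch, kind, pre, post)
    sub_plan: dict[int, tuple[str, str, str, str]] = {}
    del_plan: dict[int, str] = {}  # codon index -> branch
    ins_plan: list[tuple[int, str]] = []  # (insert before root codon i, branch)
    truth_events: dict[str, list[dict]] = {b: [] for b in _BRANCHES}
    # deletions first: same-branch DEL slots must not be adjacent, or the
    # planted runs would merge into one event
    for branch, kinds in sorted(events.items()):
        for _ in range(kinds.get("DEL", 0)):
            branch_slots = [j for j, b in del_plan.items() if b == branch]
            for idx, j in enumerate(internal):
                if all(abs(j - k) > 1 for k in branch_slots):
                    del_plan[internal.pop(idx)] = branch
                    break
            else:
                raise ValueError("cannot place non-adjacent DEL events")
    # insertions: distinct loci per branch (same-branch loci never collide)
    for branch, kinds in sorted(events.items()):
        n_ins = kinds.get("INS", 0)
        if n_ins:
            loci = rng.choice(np.arange(1, n_codons - 1), size=n_ins, replace=False)
            ins_plan.extend((int(x), branch) for x in loci)
    # substitutions take the remaining reserved slots
    for branch, kinds in sorted(events.items()):
        for kind, count in sorted(kinds.items()):
            if kind in ("INS", "DEL"):
                continue
            for _ in range(count):
                if kind == "START_LOST":
                    pre, post = _SUB_EVENTS[kind]
                    sub_plan[0] = (branch, kind, pre, post)
                else:
                    j = internal.pop()
                    pre, post = _SUB_EVENTS[kind]
                    sub_plan[j] = (branch, kind, pre, post)
    # apply substitution "pre" states to the root
    for j, (_, kind, pre, _post) in sub_plan.items():
        if kind != "START_LOST":
            root_codons[j] = pre

    # build aligned sequences segment by segment
    ins_plan.sort(key=lambda t: t[0])
    seqs = {node: [] for node in _QUARTET_NODES}
    ref_codon_counter = 0  # reference (ingroup1) codon index as segments emit

    def emit(codon_by_node: dict[str, str]) -> int | None:
        nonlocal ref_codon_counter
        for node in _QUARTET_NODES:
            seqs[node].append(codon_by_node.get(node, "---"))
        if codon_by_node.get("ingroup1", "---") != "---":
            ref_codon_counter += 1
            return ref_codon_counter - 1
        return None

    ins_iter = iter(ins_plan)
    next_ins = next(ins_iter, None)
    for j, codon in enumerate(root_codons):
        # insertions registered immediately before root codon j
        while next_ins is not None and next_ins[0] == j:
            branch = next_ins[1]
            carriers = _BRANCHES[branch]
            ins_codon = str(rng.choice(SAFE_CODONS))
            ref_idx = emit({n: ins_codon for n in carriers})
            truth_events[branch].append(
                {"kind": "INS", "root_codon": None, "ref_codon": ref_idx}
            )
            next_ins = next(ins_iter, None)
        if j in del_plan:
            branch = del_plan[j]
            absent = _BRANCHES[branch]
            ref_idx = emit(
                {n: codon for n in _QUARTET_NODES if n not in absent}
            )
            truth_events[branch].append(
                {"kind": "DEL", "root_codon": j, "ref_codon": ref_idx}
            )
        elif j in sub_plan:
            branch, kind, pre, post = sub_plan[j]
            carriers = _BRANCHES[branch]
            ref_idx = emit(
                {n: (post if n in carriers else pre) for n in _QUARTET_NODES}
            )
            truth_events[branch].append(
                {"kind": kind, "root_codon": j, "ref_codon": ref_idx}
            )
        else:
            emit({n: codon for n in _QUARTET_NODES})

    records = [
        SequenceRecord(node, "".join(seqs[node])) for node in _QUARTET_NODES
    ]
    tree = "((ingroup1,ingroup2)anc,outgroup);"
    truth = {
        "scenario": "quartet",
        "seed": int(seed),
        "n_codons": int(n_codons),
        "events": truth_events,
        "counts": {
            b: {
                k: sum(1 for e in evs if e["kind"] == k)
                for k in list(_SUB_EVENTS) + ["INS", "DEL"]
            }
            for b, evs in truth_events.items()
        },
    }
    bundle = QuartetBundle(records, tree, "ingroup1", "outgroup", truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_sequences(records, out / "alignment.fasta")
        (out / "tree.nwk").write_text(tree + "\n")
        bundle.paths = {
            "alignment": out / "alignment.fasta",
            "tree": out / "tree.nwk",
            "truth": _write_truth(truth, out),
        }
    return bundle
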
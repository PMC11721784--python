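"""End-to-end orchestration: configuration, stage wiring and the manifest.

Stages communicate only through files in the standard formats, so every
stage can be re-run independently from its inputs.  The manifest records the
package version, the seed, every threshold actually used, and per-stage row
counts, which makes a run reconstructible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .env_association import filter_collinear, permutation_test, ttest_env
from .io_formats import (
    AlleleState,
    GenomicInterval,
    GenotypeMatrix,
    read_intervals,
    read_sequences,
    read_table,
    read_variants,
)
from .orf_integrity import GeneModel, ORFCall, call_presence, extract_cds
from .population_frequency import (
    bin_frequency,
    compute_frequency,
    summarize_population,
)
from .sweep_scan import HaplotypeMatrix, call_selected, scan

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "PipelineError",
    "load_gene_models",
    "subset_gene_variants",
    "haplotypes_from_genotypes",
    "run_pipeline",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All inputs and thresholds of a pipeline run (YAML round-trippable)."""

    fasta: str = ""
    vcf: str = ""
    gff: str = ""
    pops: str = ""
    out_dir: str = "denovopop_out"
    policy: str = "strict"
    seed: int = 0
    # thresholds, each with the pipeline default
    nearly_fixed: float = 90.0
    low: float = 10.0
    tpm: float = 1.0
    identity: float = 60.0
    qcov: float = 70.0
    evalue: float = 1e-5
    grid: int = 10_000
    minwin: int = 10_000
    maxwin: int = 100_000
    top: float = 0.05
    perm: int = 1000
    collinearity: float = 0.7
    # optional stages
    env: dict = field(default_factory=dict)  # env / present / absent / factor
    sweep: dict = field(default_factory=dict)  # vcf / population / region_len

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


def load_gene_models(gff_path: str | Path) -> list[GeneModel]:
    """Build single-transcript gene models from the CDS features of a GFF3."""
    intervals = read_intervals(gff_path, "gff3")
    by_gene: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_gene.setdefault(iv.name, []).append(iv)
    models = []
    for gene_id, ivs in by_gene.items():
        strand = ivs[0].strand if ivs[0].strand in {"+", "-"} else "+"
        models.append(GeneModel(gene_id, ivs[0].chrom, strand, ivs))
    models.sort(key=lambda m: (m.chrom, m.cds_intervals[0].start))
    return models


def subset_gene_variants(
    genotypes: GenotypeMatrix, model: GeneModel
) -> GenotypeMatrix:
    """Restrict a genotype matrix to variants fully inside a gene's CDS."""
    keep = []
    for i, v in enumerate(genotypes.variants):
        span = GenomicInterval(v.chrom, v.pos0, v.pos0 + len(v.ref))
        if v.chrom == model.chrom and any(
            iv.start <= span.start and span.end <= iv.end
            for iv in model.cds_intervals
        ):
            keep.append(i)
    return GenotypeMatrix(
        genotypes.accessions,
        [genotypes.variants[i] for i in keep],
        genotypes.calls[:, keep],
    )


def haplotypes_from_genotypes(
    genotypes: GenotypeMatrix, chrom: str, population: str = "pop",
    region_start: int | None = None, region_end: int | None = None,
) -> HaplotypeMatrix:
    """Collapse homozygous diploid calls from an inbred panel to haplotypes.

    REF -> 0, ALT -> 1; HET and MISSING become missing states.
    """
    idx = [i for i, v in enumerate(genotypes.variants) if v.chrom == chrom]
    idx.sort(key=lambda i: genotypes.variants[i].pos)
    positions = [genotypes.variants[i].pos for i in idx]
    calls = genotypes.calls[:, idx]
    hap = calls.copy()
    hap[(calls == AlleleState.HET) | (calls == AlleleState.MISSING)] = -1
    return HaplotypeMatrix(
        chrom,
        positions,
        hap,
        population,
        region_start,
        region_end,
    ).drop_monomorphic()


def _calls_to_frame(calls: list[ORFCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "accession": [c.accession for c in calls],
            "gene_id": [c.gene_id for c in calls],
            "status": [c.status.value for c in calls],
            "present": [int(c.present) for c in calls],
            "events": [";".join(c.events) for c in calls],
        }
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute presence -> frequency -> summaries (plus optional stages).

    Returns the manifest dict; raises :class:`PipelineError` naming the
    failing stage on any error, after writing partial outputs under
    ``<out_dir>/failed/``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            k: getattr(config, k)
            for k in (
                "nearly_fixed", "low", "tpm", "identity", "qcov", "evalue",
                "grid", "minwin", "maxwin", "top", "perm", "collinearity",
            )
        },
        "policy": config.policy,
        "stages": {},
    }

    def fail(stage: str, err: Exception):
        manifest["stages"][stage] = {"status": "failed", "error": str(err)}
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        (failed / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise PipelineError(stage, str(err)) from err

    # --- presence
    stage = "presence"
    try:
        for key in ("fasta", "vcf", "gff", "pops"):
            p = getattr(config, key)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"input {key!r} not found: {p}")
        genome = {r.id: r for r in read_sequences(config.fasta)}
        genotypes = read_variants(config.vcf)
        models = load_gene_models(config.gff)
        all_calls: list[ORFCall] = []
        for model in models:
            cds = extract_cds(genome, model)
            sub = subset_gene_variants(genotypes, model)
            all_calls.extend(call_presence(model, sub, cds, config.policy))
        calls_df = _calls_to_frame(all_calls)
        calls_df.to_csv(out / "calls.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {"status": "ok", "rows": len(calls_df)}
    except Exception as err:  # noqa: BLE001 - stage boundary
        fail(stage, err)

    # --- frequency + summaries
    stage = "frequency"
    try:
        pops = read_table(config.pops, required=("accession", "population"))
        pop_map = dict(zip(pops.accession, pops.population))
        records = compute_frequency(all_calls, pop_map)
        freq_df = pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in records],
                "population": [r.population for r in records],
                "n_called": [r.n_called for r in records],
                "n_present": [r.n_present for r in records],
                "freq_pct": [round(r.freq_pct, 4) for r in records],
                "bin": [bin_frequency(r.freq_pct) for r in records],
            }
        )
        freq_df.to_csv(out / "frequencies.tsv", sep="\t", index=False)
        summary = summarize_population(
            records,
            nearly_fixed_threshold=config.nearly_fixed,
            low_threshold=config.low,
        )
        summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {"status": "ok", "rows": len(freq_df)}
    except Exception as err:  # noqa: BLE001
        fail(stage, err)

    # --- optional environmental stage
    if config.env:
        stage = "envtest"
        try:
            env = read_table(config.env["env"], required=("accession",))
            present = Path(config.env["present"]).read_text().split()
            absent = Path(config.env["absent"]).read_text().split()
            tt = ttest_env(env, present, absent)
            tt.to_csv(out / "ttests.tsv", sep="\t", index=False)
            factor = config.env.get("factor", "bio17")
            res = permutation_test(
                env.set_index("accession").loc[present, factor].to_numpy(),
                env.set_index("accession").loc[absent, factor].to_numpy(),
                n_perm=config.perm,
                seed=config.seed,
            )
            pd.DataFrame(
                {
                    "factor": [factor],
                    "observed_mean": [res.observed_mean],
                    "ci_low": [res.ci_low],
                    "ci_high": [res.ci_high],
                    "p_empirical": [res.p_empirical],
                    "significant": [int(res.significant)],
                }
            ).to_csv(out / "permutation.tsv", sep="\t", index=False)
            retained = filter_collinear(env, threshold=config.collinearity)
            (out / "retained_factors.txt").write_text("\n".join(retained) + "\n")
            manifest["stages"][stage] = {"status": "ok", "rows": len(tt)}
        except Exception as err:  # noqa: BLE001
            fail(stage, err)

    # --- optional sweep stage
    if config.sweep:
        stage = "sweep"
        try:
            sw_geno = read_variants(config.sweep["vcf"])
            chrom = config.sweep.get("chrom", sw_geno.variants[0].chrom)
            hap = haplotypes_from_genotypes(
                sw_geno,
                chrom,
                config.sweep.get("population", "pop"),
                config.sweep.get("region_start"),
                config.sweep.get("region_end"),
            )
            results = scan(hap, config.grid, config.minwin, config.maxwin)
            omega_df = pd.DataFrame(
                {
                    "center": [r.center for r in results],
                    "omega": [r.omega for r in results],
                    "best_window": [r.best_window for r in results],
                    "n_left": [r.n_left for r in results],
                    "n_right": [r.n_right for r in results],
                }
            )
            omega_df.to_csv(out / "omega.tsv", sep="\t", index=False)
            regions = call_selected(
                results, config.top, config.grid, chrom, hap.population
            )
            with open(out / "regions.bed", "w") as fh:
                for r in regions:
                    fh.write(
                        f"{r.interval.chrom}\t{r.interval.start}\t"
                        f"{r.interval.end}\t{r.population}\n"
                    )
            manifest["stages"][stage] = {"status": "ok", "rows": len(omega_df)}
        except Exception as err:  # noqa: BLE001
            fail(stage, err)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
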
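"""Per-population presence frequencies, frequency-spectrum bins and
frequency-class feature contrasts.

Frequencies are census proportions of accessions whose ORF call is
FUNCTIONAL among accessions with a resolved call.  The spectrum bins follow
the convention: an exact 0 and an exact 100 are their own classes, and every
other frequency falls into a decade bin labelled by its midpoint (5, 15, ...,
95) with [10k, 10(k+1)) boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .orf_integrity import ORFCall, OrfStatus

logger = logging.getLogger(__name__)

__all__ = [
    "FrequencyRecord",
    "EvidenceTier",
    "compute_frequency",
    "bin_frequency",
    "summarize_population",
    "compare_features",
    "compute_gc",
    "compute_cds_length",
    "classify_evidence",
]


@dataclass(frozen=True)
class FrequencyRecord:
    gene_id: str
    population: str
    n_called: int
    n_present: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_present <= self.n_called):
            raise ValueError("need 0 <= n_present <= n_called")

    @property
    def freq_pct(self) -> float:
        return 100.0 * self.n_present / self.n_called


def compute_frequency(
    calls: Iterable[ORFCall], pop_map: Mapping[str, str]
) -> list[FrequencyRecord]:
    """Aggregate ORF calls into per-gene, per-population presence frequencies.

    UNRESOLVED calls shrink the denominator rather than counting as absent.
    Gene x population combinations with zero resolved calls are omitted with
    a warning.
    """
    counts: dict[tuple[str, str], list[int]] = {}
    genes: list[str] = []
    pops: list[str] = []
    for call in calls:
        if call.accession not in pop_map:
            raise KeyError(f"accession {call.accession!r} missing from pop_map")
        pop = pop_map[call.accession]
        if call.gene_id not in genes:
            genes.append(call.gene_id)
        if pop not in pops:
            pops.append(pop)
        if call.status is OrfStatus.UNRESOLVED:
            continue
        key = (call.gene_id, pop)
        n = counts.setdefault(key, [0, 0])
        n[0] += 1
        n[1] += int(call.present)
    records = []
    for gene in genes:
        for pop in pops:
            if (gene, pop) in counts:
                n_called, n_present = counts[(gene, pop)]
                records.append(FrequencyRecord(gene, pop, n_called, n_present))
            else:
                logger.warning(
                    "gene %s, population %s: no resolved calls, record omitted",
                    gene,
                    pop,
                )
    return records


def bin_frequency(freq_pct: float) -> str:
    """Spectrum bin label for a presence frequency in percent.

    0 and 100 are exact classes; otherwise decade bins labelled by midpoint:
    0 < f < 10 -> "5", 10 <= f < 20 -> "15", ..., 90 <= f < 100 -> "95".
    """
    if not 0 <= freq_pct <= 100:
        raise ValueError(f"frequency {freq_pct} outside [0, 100]")
    if freq_pct == 0:
        return "0"
    if freq_pct == 100:
        return "100"
    return str(10 * int(freq_pct // 10) + 5)


def summarize_population(
    records: Iterable[FrequencyRecord],
    nearly_fixed_threshold: float = 90.0,
    low_threshold: float = 10.0,
    nearly_fixed_strict: bool = True,
) -> pd.DataFrame:
    """Per-population fractions of nearly-fixed and low-frequency genes.

    Defaults follow the strict reading "nearly fixed (frequency > 90%)" and
    "low frequency (< 10%)"; set ``nearly_fixed_strict=False`` for a >=
    threshold.
    """
    recs = list(records)
    if not recs:
        raise ValueError("no frequency records to summarize")
    rows = []
    for pop in sorted({r.population for r in recs}):
        freqs = np.array([r.freq_pct for r in recs if r.population == pop])
        if nearly_fixed_strict:
            nearly = np.mean(freqs > nearly_fixed_threshold)
        else:
            nearly = np.mean(freqs >= nearly_fixed_threshold)
        rows.append(
            {
                "population": pop,
                "n_genes": len(freqs),
                "nearly_fixed_fraction": float(nearly),
                "low_fraction": float(np.mean(freqs < low_threshold)),
            }
        )
    return pd.DataFrame(rows)


def compare_features(
    features: pd.DataFrame,
    low_set: Sequence[str],
    high_set: Sequence[str],
    feature_columns: Sequence[str] | None = None,
    gene_column: str = "gene_id",
) -> pd.DataFrame:
    """Contrast gene features between low- and high-frequency gene classes.

    Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value per feature,
    Benjamini-Hochberg adjusted across the feature list; the direction of the
    median difference (high minus low) is reported.  A feature entirely
    missing in either class is skipped with a warning.
    """
    if not len(low_set) or not len(high_set):
        raise ValueError("both gene sets must be non-empty")
    df = features.set_index(gene_column)
    if feature_columns is None:
        feature_columns = [
            c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])
        ]
    rows = []
    for col in feature_columns:
        low = df.loc[df.index.intersection(low_set), col].dropna().to_numpy(float)
        high = df.loc[df.index.intersection(high_set), col].dropna().to_numpy(float)
        if len(low) == 0 or len(high) == 0:
            logger.warning("feature %s entirely missing in one class; skipped", col)
            continue
        med_low = float(np.median(low))
        med_high = float(np.median(high))
        pooled = np.concatenate([low, high])
        if np.all(pooled == pooled[0]):
            p = 1.0  # constant feature: no rank information
        else:
            p = float(
                stats.mannwhitneyu(low, high, alternative="two-sided").pvalue
            )
        rows.append(
            {
                "feature": col,
                "n_low": len(low),
                "n_high": len(high),
                "median_low": med_low,
                "median_high": med_high,
                "direction": int(np.sign(med_high - med_low)),
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def compute_gc(seq: str) -> float:
    """GC fraction over A/C/G/T; N (and gaps) excluded from the denominator."""
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        return float("nan")
    return (counts["G"] + counts["C"]) / denom


def compute_cds_length(model) -> int:
    return model.cds_length


class EvidenceTier(Enum):
    TN = "TN"  # no transcription or translation evidence
    TC = "TC"  # transcription only (TPM > 1 somewhere)
    TL_MINUS = "TL-"  # translated, no poly(A) tail
    TL_PLUS = "TL+"  # translated with poly(A) tail


def classify_evidence(
    tpm_by_tissue: Mapping[str, float], translated: bool, polya: bool,
    tpm_threshold: float = 1.0,
) -> EvidenceTier:
    """Evidence tier from expression and translation flags.

    Expression presence means TPM strictly greater than the threshold (1 by
    default) in at least one tissue.
    """
    if translated:
        return EvidenceTier.TL_PLUS if polya else EvidenceTier.TL_MINUS
    if any(v > tpm_threshold for v in tpm_by_tissue.values()):
        return EvidenceTier.TC
    return EvidenceTier.TN
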
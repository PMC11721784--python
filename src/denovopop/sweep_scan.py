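"""Linkage-disequilibrium contrast scan for completed selective sweeps.

The omega statistic at a focal point compares the average r-squared within
the two flanks of the point against the average r-squared between them: a
completed sweep leaves two internally correlated flank haplotype blocks with
little cross-flank association, so omega peaks at the swept site.  The scan
evaluates omega on a regular grid (10 kb by default) maximised over a ladder
of symmetric window extents between a minimum and maximum size, and calls
the top fraction of the genome-wide values as selected regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "HaplotypeMatrix",
    "OmegaResult",
    "SelectedRegion",
    "GeneSelectionSummary",
    "r_squared",
    "r_squared_matrix",
    "omega_at",
    "scan",
    "call_selected",
    "overlap_genes",
    "compute_pi",
]

OMEGA_CAP = 1e6  # sentinel when the cross-flank LD sum is exactly zero
MISSING = -1


@dataclass
class HaplotypeMatrix:
    """Binary haplotype states (0 ancestral/ref, 1 derived/alt, -1 missing)."""

    chrom: str
    positions: np.ndarray  # bp, strictly increasing
    haplotypes: np.ndarray  # (n_hap, n_site) int8
    population: str = "pop"
    region_start: int | None = None
    region_end: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.haplotypes.shape[1] != len(self.positions):
            raise ValueError("haplotype matrix width must match positions")
        if self.region_start is None:
            self.region_start = int(self.positions[0]) if len(self.positions) else 0
        if self.region_end is None:
            self.region_end = int(self.positions[-1]) + 1 if len(self.positions) else 0

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_site(self) -> int:
        return self.haplotypes.shape[1]

    def drop_monomorphic(self) -> "HaplotypeMatrix":
        """Ingestion filter: remove sites with fewer than 2 observed alleles."""
        keep = []
        for j in range(self.n_site):
            col = self.haplotypes[:, j]
            obs = col[col != MISSING]
            if len(np.unique(obs)) >= 2:
                keep.append(j)
        return HaplotypeMatrix(
            self.chrom,
            self.positions[keep],
            self.haplotypes[:, keep],
            self.population,
            self.region_start,
            self.region_end,
        )


@dataclass
class OmegaResult:
    center: int
    omega: float  # nan when undefined
    best_window: int | None
    n_left: int
    n_right: int


@dataclass(frozen=True)
class SelectedRegion:
    interval: GenomicInterval
    population: str


@dataclass
class GeneSelectionSummary:
    per_population: dict[str, int]
    selected_populations: dict[str, set[str]]  # gene -> populations
    union_count: int
    union_pct: float
    shared_by_k: dict[int, int]


# ---------------------------------------------------------------------------
# Linkage disequilibrium


def r_squared(site_i: np.ndarray, site_j: np.ndarray) -> float:
    """Squared allelic correlation between two sites, pairwise-complete.

    Returns nan when either site is monomorphic in the haplotypes observed at
    both sites.
    """
    a = np.asarray(site_i)
    b = np.asarray(site_j)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok].astype(float), b[ok].astype(float)
    if len(a) == 0:
        return float("nan")
    p, q = a.mean(), b.mean()
    if p in (0.0, 1.0) or q in (0.0, 1.0):
        return float("nan")
    d = (a * b).mean() - p * q
    return float(d * d / (p * (1 - p) * q * (1 - q)))


def r_squared_matrix(hap: HaplotypeMatrix) -> np.ndarray:
    """All-pairs r-squared; vectorised when the matrix has no missing data."""
    H = hap.haplotypes
    if not np.any(H == MISSING):
        X = H.astype(float)
        X -= X.mean(axis=0)
        sd = X.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            Z = X / sd
            r = (Z.T @ Z) / H.shape[0]
        out = r * r
        out[~np.isfinite(out)] = np.nan
        return out
    n = hap.n_site
    out = np.full((n, n), np.nan)
    for i in range(n):
        out[i, i] = 1.0
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = r_squared(H[:, i], H[:, j])
    return out


# ---------------------------------------------------------------------------
# Omega


def _window_ladder(minwin: int, maxwin: int, n_windows: int) -> np.ndarray:
    return np.unique(
        np.round(np.geomspace(minwin, maxwin, n_windows)).astype(int)
    )


def _flank_sums(r2: np.ndarray, left: np.ndarray, right: np.ndarray):
    sub_ll = r2[np.ix_(left, left)]
    sub_rr = r2[np.ix_(right, right)]
    sub_lr = r2[np.ix_(left, right)]
    iu_l = np.triu_indices(len(left), k=1)
    iu_r = np.triu_indices(len(right), k=1)
    within = np.concatenate([sub_ll[iu_l], sub_rr[iu_r]])
    cross = sub_lr.ravel()
    return within, cross


def omega_at(
    hap: HaplotypeMatrix,
    center: int,
    minwin: int = 10_000,
    maxwin: int = 100_000,
    n_windows: int = 10,
    r2: np.ndarray | None = None,
) -> OmegaResult:
    """Maximised omega at one focal position over a geometric window ladder.

    For each symmetric extent w, the left flank holds sites in
    [center - w, center] and the right flank sites in (center, center + w];
    omega(w) is the ratio of the average within-flank r-squared to the
    average cross-flank r-squared.  The maximum over the ladder is returned.
    A window needs at least 2 sites per flank; when the cross-flank sum is
    exactly 0 with a positive numerator the capped sentinel is emitted.
    """
    if r2 is None:
        r2 = r_squared_matrix(hap)
    pos = hap.positions
    best: tuple[float, int, int, int] | None = None
    for w in _window_ladder(minwin, maxwin, n_windows):
        left = np.flatnonzero((pos >= center - w) & (pos <= center))
        right = np.flatnonzero((pos > center) & (pos <= center + w))
        l, r = len(left), len(right)
        if l < 2 or r < 2:
            continue
        within, cross = _flank_sums(r2, left, right)
        n_within = np.sum(np.isfinite(within))
        n_cross = np.sum(np.isfinite(cross))
        if n_within == 0 or n_cross == 0:
            continue
        num = np.nansum(within) / n_within
        den = np.nansum(cross) / n_cross
        if den == 0:
            omega = OMEGA_CAP if num > 0 else 0.0
        else:
            omega = float(num / den)
        if best is None or omega > best[0]:
            best = (omega, int(w), l, r)
    if best is None:
        return OmegaResult(center, float("nan"), None, 0, 0)
    return OmegaResult(center, best[0], best[1], best[2], best[3])


def scan(
    hap: HaplotypeMatrix,
    grid_step: int = 10_000,
    minwin: int = 10_000,
    maxwin: int = 100_000,
    n_windows: int = 10,
) -> list[OmegaResult]:
    """Omega at every grid point strictly inside the region span."""
    if hap.region_end - hap.region_start < grid_step:
        raise ValueError("region shorter than one grid step")
    r2 = r_squared_matrix(hap)
    centers = [
        c
        for c in range(
            (hap.region_start // grid_step + 1) * grid_step,
            hap.region_end,
            grid_step,
        )
    ]
    return [
        omega_at(hap, c, minwin, maxwin, n_windows, r2=r2) for c in centers
    ]


def call_selected(
    results: Sequence[OmegaResult],
    top_frac: float = 0.05,
    grid_step: int = 10_000,
    chrom: str = "1",
    population: str = "pop",
    merge: bool = True,
) -> list[SelectedRegion]:
    """Call the top fraction of finite omega values as selected regions.

    The threshold is the (1 - top_frac) quantile of the finite values
    genome-wide; grid points at or above it (ties included) become regions
    [center - step/2, center + step/2), merged when adjacent.
    """
    finite = [r for r in results if np.isfinite(r.omega)]
    if not finite:
        logger.warning("no finite omega values; no regions called")
        return []
    if len(finite) < 20:
        logger.warning(
            "only %d finite omega values; a %.0f%% cut is poorly resolved",
            len(finite),
            100 * top_frac,
        )
    threshold = float(np.quantile([r.omega for r in finite], 1 - top_frac))
    half = grid_step // 2
    spans = sorted(
        (r.center - half, r.center + half)
        for r in finite
        if r.omega >= threshold
    )
    merged: list[list[int]] = []
    for s, e in spans:
        if merge and merged and merged[-1][1] >= s:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [
        SelectedRegion(GenomicInterval(chrom, max(0, s), e, population), population)
        for s, e in merged
    ]


def overlap_genes(
    regions: Iterable[SelectedRegion],
    genes: Sequence[GenomicInterval],
    catalog_size: int | None = None,
) -> GeneSelectionSummary:
    """Summarise which genes overlap (>= 1 bp) selected regions per population.

    ``catalog_size`` defaults to the number of gene intervals supplied and is
    the denominator of the union percentage.
    """
    selected: dict[str, set[str]] = {}
    per_pop: dict[str, int] = {}
    regions = list(regions)
    pops = sorted({r.population for r in regions})
    for pop in pops:
        pop_regions = [r for r in regions if r.population == pop]
        count = 0
        for gene in genes:
            if any(gene.overlaps(r.interval) for r in pop_regions):
                selected.setdefault(gene.name, set()).add(pop)
                count += 1
        per_pop[pop] = count
    union = len(selected)
    size = catalog_size if catalog_size is not None else len(genes)
    shared_by_k: dict[int, int] = {}
    for pops_for_gene in selected.values():
        k = len(pops_for_gene)
        shared_by_k[k] = shared_by_k.get(k, 0) + 1
    return GeneSelectionSummary(
        per_population=per_pop,
        selected_populations=selected,
        union_count=union,
        union_pct=100.0 * union / size if size else float("nan"),
        shared_by_k=dict(sorted(shared_by_k.items())),
    )


# ---------------------------------------------------------------------------
# Nucleotide diversity


def compute_pi(hap: HaplotypeMatrix) -> float:
    """Average pairwise difference per site across the matrix columns.

    Per site, the unbiased heterozygosity 2 p (1-p) n / (n-1) over observed
    haplotypes; averaged over all columns of the matrix.
    """
    if hap.n_hap < 2:
        raise ValueError("need at least 2 haplotypes")
    total = 0.0
    for j in range(hap.n_site):
        col = hap.haplotypes[:, j]
        obs = col[col != MISSING].astype(float)
        n = len(obs)
        if n < 2:
            continue
        p = obs.mean()
        total += 2 * p * (1 - p) * n / (n - 1)
    return total / hap.n_site if hap.n_site else 0.0
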
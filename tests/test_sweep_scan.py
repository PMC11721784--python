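import itertools
import math

import numpy as np
import pytest

from denovopop.io_formats import GenomicInterval
from denovopop.sweep_scan import (
    OMEGA_CAP,
    HaplotypeMatrix,
    OmegaResult,
    SelectedRegion,
    call_selected,
    compute_pi,
    omega_at,
    overlap_genes,
    r_squared,
    r_squared_matrix,
    scan,
)


def matrix(haps, positions=None, **kw):
    haps = np.asarray(haps, dtype=np.int8)
    if positions is None:
        positions = np.arange(1, haps.shape[1] + 1)
    return HaplotypeMatrix("1", positions, haps, **kw)


def r2_oracle(a, b):
    """2x2 count-table oracle for r-squared."""
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok], b[ok]
    n = len(a)
    p11 = np.sum((a == 1) & (b == 1)) / n
    p = a.mean()
    q = b.mean()
    if p in (0, 1) or q in (0, 1):
        return float("nan")
    d = p11 - p * q
    return d * d / (p * (1 - p) * q * (1 - q))


class TestRSquared:
    def test_complete_association(self):
        h = np.array([[1, 1], [1, 1], [0, 0], [0, 0]])
        assert r_squared(h[:, 0], h[:, 1]) == pytest.approx(1.0)

    def test_independence(self):
        h = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
        assert r_squared(h[:, 0], h[:, 1]) == pytest.approx(0.0)

    def test_partial_association_matches_count_table(self):
        h = np.array([[1, 1], [1, 1], [1, 0], [0, 0]])
        got = r_squared(h[:, 0], h[:, 1])
        assert got == pytest.approx(r2_oracle(h[:, 0], h[:, 1]))

    def test_monomorphic_pairwise_complete_subset_undefined(self):
        a = np.array([1, 1, 0, -1])
        b = np.array([1, 1, -1, 0])  # complete subset: a = 1,1 monomorphic
        assert math.isnan(r_squared(a, b))

    def test_oracle_battery_with_missing(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(4, 12))
            a = rng.integers(0, 2, n)
            b = rng.integers(0, 2, n)
            a[rng.random(n) < 0.2] = -1
            b[rng.random(n) < 0.2] = -1
            got = r_squared(a, b)
            want = r2_oracle(a, b) if np.any((a >= 0) & (b >= 0)) else float("nan")
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want)

    def test_matrix_agrees_with_pairwise(self):
        rng = np.random.default_rng(1)
        haps = rng.integers(0, 2, size=(20, 8)).astype(np.int8)
        m = matrix(haps)
        full = r_squared_matrix(m)
        for i, j in itertools.combinations(range(8), 2):
            want = r_squared(haps[:, i], haps[:, j])
            if math.isnan(want):
                assert math.isnan(full[i, j])
            else:
                assert full[i, j] == pytest.approx(want)


def omega_oracle(hap, center, minwin, maxwin, n_windows=10):
    """Direct evaluation of the omega formula by exhaustive pair summation."""
    best = None
    for w in np.unique(np.round(np.geomspace(minwin, maxwin, n_windows)).astype(int)):
        left = [i for i, p in enumerate(hap.positions) if center - w <= p <= center]
        right = [i for i, p in enumerate(hap.positions) if center < p <= center + w]
        if len(left) < 2 or len(right) < 2:
            continue
        wl = [r_squared(hap.haplotypes[:, i], hap.haplotypes[:, j])
              for i, j in itertools.combinations(left, 2)]
        wr = [r_squared(hap.haplotypes[:, i], hap.haplotypes[:, j])
              for i, j in itertools.combinations(right, 2)]
        cr = [r_squared(hap.haplotypes[:, i], hap.haplotypes[:, j])
              for i in left for j in right]
        within = [x for x in wl + wr if not math.isnan(x)]
        cross = [x for x in cr if not math.isnan(x)]
        if not within or not cross:
            continue
        num = sum(within) / len(within)
        den = sum(cross) / len(cross)
        omega = OMEGA_CAP if den == 0 and num > 0 else (
            0.0 if den == 0 else num / den
        )
        if best is None or omega > best:
            best = omega
    return best


class TestOmega:
    def test_uniform_ld_gives_unity(self):
        # every column identical: all pairwise r-squared are exactly 1
        col = np.array([0, 0, 1, 1], dtype=np.int8)
        haps = np.tile(col[:, None], (1, 8))
        m = matrix(haps, positions=np.arange(10, 90, 10))
        res = omega_at(m, 45, minwin=40, maxwin=40, n_windows=1)
        assert res.omega == pytest.approx(1.0)

    def test_zero_cross_ld_hits_cap(self):
        left = np.array([0, 0, 1, 1], dtype=np.int8)
        right = np.array([0, 1, 0, 1], dtype=np.int8)
        haps = np.stack([left, left, right, right], axis=1)
        m = matrix(haps, positions=[10, 20, 30, 40])
        res = omega_at(m, 25, minwin=20, maxwin=20, n_windows=1)
        assert res.omega == OMEGA_CAP

    def test_matches_bruteforce_on_random_configurations(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n_sites = int(rng.integers(6, 12))
            haps = rng.integers(0, 2, size=(16, n_sites)).astype(np.int8)
            m = matrix(haps, positions=np.sort(
                rng.choice(np.arange(1, 200), n_sites, replace=False)))
            m = m.drop_monomorphic()
            if m.n_site < 4:
                continue
            center = 100
            got = omega_at(m, center, minwin=50, maxwin=150, n_windows=4)
            want = omega_oracle(m, center, 50, 150, 4)
            if want is None:
                assert math.isnan(got.omega)
            else:
                assert got.omega == pytest.approx(want)

    def test_relabel_invariance(self):
        rng = np.random.default_rng(3)
        haps = rng.integers(0, 2, size=(20, 10)).astype(np.int8)
        m = matrix(haps, positions=np.arange(10, 110, 10)).drop_monomorphic()
        a = omega_at(m, 55, minwin=50, maxwin=50, n_windows=1)
        flipped = m.haplotypes.copy()
        flipped[:, 0] = 1 - flipped[:, 0]
        b = omega_at(matrix(flipped, positions=m.positions), 55,
                     minwin=50, maxwin=50, n_windows=1)
        assert a.omega == pytest.approx(b.omega, nan_ok=True)

    def test_insufficient_sites_is_na(self):
        m = matrix(np.array([[0, 1], [1, 0], [0, 0], [1, 1]]), positions=[10, 20])
        assert math.isnan(omega_at(m, 15, minwin=10, maxwin=10).omega)


class TestScan:
    def test_grid_count_over_100kb(self):
        rng = np.random.default_rng(4)
        haps = rng.integers(0, 2, size=(10, 50)).astype(np.int8)
        m = matrix(haps, positions=np.sort(
            rng.choice(np.arange(1, 100_000), 50, replace=False)),
            region_start=0, region_end=100_000)
        results = scan(m, grid_step=10_000)
        assert len(results) == 9
        assert [r.center for r in results] == list(range(10_000, 100_000, 10_000))

    def test_region_shorter_than_step_rejected(self):
        m = matrix(np.array([[0, 1], [1, 0]]), positions=[10, 20],
                   region_start=0, region_end=100)
        with pytest.raises(ValueError):
            scan(m, grid_step=10_000)


class TestCallSelected:
    def results(self, omegas, step=10_000):
        return [
            OmegaResult(step * (i + 1), w, step, 5, 5)
            for i, w in enumerate(omegas)
        ]

    def test_exactly_top_five_of_100(self):
        rng = np.random.default_rng(5)
        omegas = list(rng.permutation(np.arange(100, dtype=float)))
        regions = call_selected(self.results(omegas), 0.05, 10_000)
        total = sum(len(r.interval) for r in regions)
        assert total == 5 * 10_000

    def test_adjacent_selected_merged(self):
        omegas = [1.0] * 98 + [50.0, 60.0]  # two adjacent top grid points
        regions = call_selected(self.results(omegas), 0.02, 10_000)
        assert len(regions) == 1
        assert len(regions[0].interval) == 20_000

    def test_merge_disabled(self):
        omegas = [1.0] * 98 + [50.0, 60.0]
        regions = call_selected(self.results(omegas), 0.02, 10_000, merge=False)
        assert len(regions) == 2

    def test_all_na_empty(self):
        nas = [OmegaResult(10_000, float("nan"), None, 0, 0)]
        assert call_selected(nas, 0.05, 10_000) == []

    def test_ties_at_cut_included(self):
        omegas = [1.0] * 90 + [9.0] * 10
        regions = call_selected(self.results(omegas), 0.05, 10_000)
        total = sum(len(r.interval) for r in regions)
        assert total == 10 * 10_000  # all tied values at the cut retained


class TestOverlap:
    def region(self, start, end, pop="P1"):
        return SelectedRegion(GenomicInterval("1", start, end, pop), pop)

    def test_gene_inside_region_selected(self):
        genes = [GenomicInterval("1", 120, 180, "g1")]
        s = overlap_genes([self.region(100, 200)], genes)
        assert s.union_count == 1 and s.per_population == {"P1": 1}

    def test_abutting_half_open_not_selected(self):
        genes = [GenomicInterval("1", 200, 250, "g1")]
        s = overlap_genes([self.region(100, 200)], genes)
        assert s.union_count == 0

    def test_union_percentage_and_sharing(self):
        genes = [GenomicInterval("1", i * 1000, i * 1000 + 100, f"g{i}")
                 for i in range(10)]
        regions = [self.region(0, 1200, "P1"), self.region(0, 2200, "P2")]
        s = overlap_genes(regions, genes)
        assert s.per_population == {"P1": 2, "P2": 3}
        assert s.union_count == 3
        assert s.union_pct == pytest.approx(30.0)
        assert s.shared_by_k == {1: 1, 2: 2}


def pi_oracle(haps):
    """Mean over all haplotype pairs of per-site Hamming distance / L."""
    n, L = haps.shape
    total = 0.0
    pairs = 0
    for i, j in itertools.combinations(range(n), 2):
        total += np.sum(haps[i] != haps[j]) / L
        pairs += 1
    return total / pairs


class TestPi:
    def test_identical_haplotypes(self):
        assert compute_pi(matrix(np.zeros((4, 10)) + 1)) == 0.0

    def test_one_difference_in_ten_sites(self):
        haps = np.zeros((2, 10), dtype=np.int8)
        haps[1, 3] = 1
        assert compute_pi(matrix(haps)) == pytest.approx(0.1)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            haps = rng.integers(0, 2, size=(int(rng.integers(2, 8)),
                                            int(rng.integers(2, 15)))).astype(np.int8)
            assert compute_pi(matrix(haps)) == pytest.approx(pi_oracle(haps))

    def test_single_haplotype_rejected(self):
        with pytest.raises(ValueError):
            compute_pi(matrix(np.zeros((1, 5))))
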
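"""Windowed pi / D_XY: per-site formulas, pair-enumeration oracle, filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import regmark.diversity as div
from regmark.evaluation import pairwise_dxy, pairwise_pi, window_oracle
from regmark.model import GenotypeMatrix
from tests.conftest import make_peak


def make_matrix(pos, geno, n_per_pop, length=100_000):
    samples = [f"a{i}" for i in range(n_per_pop)] + [
        f"b{i}" for i in range(n_per_pop)
    ]
    pops = {s: ("p1" if s.startswith("a") else "p2") for s in samples}
    return GenotypeMatrix(
        samples, pops,
        {"chr1": (np.asarray(pos, dtype=np.int64),
                  np.asarray(geno, dtype=np.int8))},
        chrom_lengths={"chr1": length},
    )


class TestSiteStatistics:
    def test_pi_four_alleles_two_alt(self):
        # C(4,2) = 6 pairs, 2x2 = 4 differ -> 2/3
        assert div.site_pi(4, 2) == pytest.approx(2 / 3)

    @pytest.mark.parametrize("m,c", [(4, 0), (4, 4), (2, 0), (10, 10)])
    def test_pi_monomorphic_is_zero(self, m, c):
        assert div.site_pi(m, c) == 0.0

    def test_pi_requires_two_alleles(self):
        with pytest.raises(ValueError):
            div.site_pi(1, 0)

    @given(m=st.integers(2, 20), c=st.integers(0, 20))
    @settings(deadline=None, derandomize=True)
    def test_pi_matches_pair_enumeration(self, m, c):
        if c > m:
            return
        # enumerate all allele pairs directly
        alleles = [1] * c + [0] * (m - c)
        diff = sum(
            alleles[i] != alleles[j]
            for i in range(m) for j in range(i + 1, m)
        )
        pairs = m * (m - 1) / 2
        assert div.site_pi(m, c) == pytest.approx(diff / pairs)

    def test_dxy_fixed_difference(self):
        assert div.site_dxy(4, 4, 4, 0) == 1.0

    @given(m=st.integers(1, 12), c=st.integers(0, 12))
    @settings(deadline=None, derandomize=True)
    def test_dxy_equal_frequencies_identity(self, m, c):
        if c > m:
            return
        p = c / m
        assert div.site_dxy(m, c, m, c) == pytest.approx(2 * p * (1 - p))

    @given(
        m1=st.integers(1, 10), c1=st.integers(0, 10),
        m2=st.integers(1, 10), c2=st.integers(0, 10),
    )
    @settings(deadline=None, derandomize=True)
    def test_dxy_population_swap_symmetry(self, m1, c1, m2, c2):
        if c1 > m1 or c2 > m2:
            return
        assert div.site_dxy(m1, c1, m2, c2) == pytest.approx(
            div.site_dxy(m2, c2, m1, c1)
        )


class TestWindows:
    def test_stated_arithmetic_example(self):
        """12 SNPs each with site pi = 2/3 in one 10-kb window:
        pi = 12 * (2/3) / 10000 = 8e-4."""
        pos = np.arange(100, 1300, 100)[:12]
        # 2 diploids per pop, one het + one het -> m=4, c=2 -> pi = 2/3
        geno = np.tile([1, 1, 1, 1], (12, 1))
        gm = make_matrix(pos, geno, 2, length=10_000)
        (w,) = div.windowed_diversity(gm, window=10_000, min_snps=10)
        assert w.pi["p1"] == pytest.approx(8e-4)
        assert w.pi["p2"] == pytest.approx(8e-4)
        assert w.n_snps == 12

    def test_sparse_window_dropped(self):
        pos = [100, 200]
        geno = np.tile([1, 0, 1, 0], (2, 1))
        gm = make_matrix(pos, geno, 2, length=10_000)
        assert div.windowed_diversity(gm, window=10_000, min_snps=10) == []
        assert len(div.windowed_diversity(gm, window=10_000, min_snps=2)) == 1

    def test_monomorphic_matrix_yields_no_windows(self):
        pos = np.arange(0, 2000, 100)
        geno = np.zeros((len(pos), 4))
        gm = make_matrix(pos, geno, 2, length=10_000)
        ws = div.windowed_diversity(gm, window=10_000, min_snps=10)
        # sites exist but are monomorphic: window kept, statistics zero
        assert all(w.pi["p1"] == 0 and w.dxy == 0 for w in ws)

    def test_partial_trailing_window_flagged(self):
        pos = np.arange(10_100, 12_000, 100)
        geno = np.tile([1, 0, 1, 0], (len(pos), 1))
        gm = make_matrix(pos, geno, 2, length=12_000)
        ws = div.windowed_diversity(gm, window=10_000, min_snps=10)
        (w,) = ws
        assert w.partial and w.accessible == 2_000
        assert w.interval.start == 10_000 and w.interval.end == 12_000

    def test_missing_genotypes_reduce_m(self):
        # one site: pop1 genotypes {1, missing} -> m=2, c=1 -> pi = 1
        pos = [50] * 1
        geno = [[1, -1, 0, 0]]
        gm = make_matrix(pos, geno, 2, length=10_000)
        (w,) = div.windowed_diversity(gm, window=10_000, min_snps=1)
        assert w.pi["p1"] == pytest.approx(1.0 / 10_000)

    def test_matches_pairwise_enumeration_oracle(self):
        """Vectorised windowed statistics vs brute-force pair enumeration on
        random matrices with missing data (tolerance 1e-12)."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            n_per_pop = int(rng.integers(2, 11))
            n_sites = int(rng.integers(20, 200))
            pos = np.sort(rng.choice(50_000, size=n_sites, replace=False))
            geno = rng.integers(0, 3, size=(n_sites, 2 * n_per_pop))
            geno[rng.random(geno.shape) < 0.1] = -1
            gm = make_matrix(pos, geno, n_per_pop, length=50_000)
            ws = div.windowed_diversity(gm, window=10_000, min_snps=1)
            oracle = window_oracle(gm, {"chr1": 50_000}, window=10_000,
                                   min_snps=1)
            assert len(ws) == len(oracle)
            for w, o in zip(ws, oracle):
                assert abs(w.pi["p1"] - o["pi"]["p1"]) < 1e-12
                assert abs(w.pi["p2"] - o["pi"]["p2"]) < 1e-12
                assert abs(w.dxy - o["dxy"]) < 1e-12

    def test_relabeling_within_population_invariance(self, rng):
        pos = np.sort(rng.choice(10_000, size=30, replace=False))
        geno = rng.integers(0, 3, size=(30, 8))
        gm = make_matrix(pos, geno, 4, length=10_000)
        perm = np.concatenate([rng.permutation(4), 4 + rng.permutation(4)])
        gm2 = make_matrix(pos, geno[:, perm], 4, length=10_000)
        (w1,), (w2,) = (
            div.windowed_diversity(g, window=10_000, min_snps=1)
            for g in (gm, gm2)
        )
        assert w1.pi == pytest.approx(w2.pi)
        assert w1.dxy == pytest.approx(w2.dxy)


class TestPeakOverlap:
    def _windows(self, theta_scale_in, rng, n=40):
        from regmark.simulate import SimulationConfig, simulate_genotypes

        length = n * 10_000
        peaks = [
            make_peak("chr1", s, s + 10_000)
            for s in range(0, length, 20_000)
        ]
        cfg = SimulationConfig(
            seed=0, theta_out=0.005, theta_in=0.005 * theta_scale_in,
            chrom_len=max(length, 100_000),
        )
        gm = simulate_genotypes(cfg, peaks, {"chr1": length}, rng)
        ws = div.windowed_diversity(gm, {"chr1": length}, window=10_000,
                                    min_snps=10)
        return ws, peaks

    def test_planted_elevation_detected(self, rng):
        ws, peaks = self._windows(2.0, rng, n=60)
        comp = div.compare_peak_overlap(ws, peaks)
        assert comp.pi_median_in > comp.pi_median_out
        assert comp.pi_p < 1e-3 and comp.dxy_p < 1e-3

    def test_empty_group_rejected(self, rng):
        ws, _ = self._windows(1.0, rng)
        with pytest.raises(ValueError):
            div.compare_peak_overlap(ws, [make_peak("chr9", 0, 100)])

    def test_overlap_flag_one_bp_rule(self):
        pos = np.arange(0, 2000, 100)
        geno = np.tile([1, 0, 1, 0], (len(pos), 1))
        gm = make_matrix(pos, geno, 2, length=10_000)
        (w,) = div.windowed_diversity(gm, window=10_000, min_snps=10)
        assert div.flag_peak_overlap([w], [make_peak("chr1", 9_999, 10_500)])[0]
        assert not div.flag_peak_overlap([w], [make_peak("chr1", 10_000, 10_500)])[0]
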
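"""Peak-center classification: windows, precedence, oracle agreement."""

import numpy as np
import pytest

from regmark.annotate import (
    Category,
    GeneIndex,
    annotate_peaks,
    classify_peak,
    peak_center,
    promoter_window,
    summarize_annotation,
    tts_window,
)
from regmark.evaluation import oracle_classify, paint_genome
from regmark.simulate import SimulationConfig, simulate_annotation
from tests.conftest import make_gene, make_peak


@pytest.mark.parametrize(
    "start,end,center",
    [(999, 2000, 1499), (0, 1, 0), (10, 12, 11), (10, 13, 11)],
)
def test_peak_center_floor_rule(start, end, center):
    assert peak_center(make_peak("chr1", start, end)) == center


class TestWindows:
    def test_promoter_plus_strand(self):
        g = make_gene("g", "chr1", 5000, 9001, "+")
        w = promoter_window(g)
        assert (w.start, w.end) == (4000, 5101)  # -1 kb .. +100 bp inclusive

    def test_promoter_minus_strand_mirrored(self):
        g = make_gene("g", "chr1", 1000, 5001, "-")  # tss = 5000
        w = promoter_window(g)
        assert (w.start, w.end) == (4900, 6001)

    def test_promoter_clipped_at_origin(self):
        g = make_gene("g", "chr1", 500, 2000, "+")
        w = promoter_window(g)
        assert (w.start, w.end) == (0, 601)

    def test_tts_plus_strand(self):
        g = make_gene("g", "chr1", 5000, 9001, "+")  # tts = 9000
        w = tts_window(g)
        assert (w.start, w.end) == (8900, 10001)

    def test_tts_minus_strand_mirrored(self):
        g = make_gene("g", "chr1", 9000, 12000, "-")  # tts = 9000
        w = tts_window(g)
        assert (w.start, w.end) == (8000, 9101)

    def test_tts_clipped_at_chrom_end(self):
        g = make_gene("g", "chr1", 5000, 9001, "+")
        w = tts_window(g, chrom_size=9500)
        assert w.end == 9500

    def test_unstranded_gene_rejected(self):
        g = make_gene("g", "chr1", 5000, 9001, ".")
        with pytest.raises(ValueError):
            promoter_window(g)
        with pytest.raises(ValueError):
            tts_window(g)


class TestClassify:
    def make_index(self):
        genes = [
            make_gene("gA", "chr1", 10_000, 20_000, "+",
                      exons=[(10_000, 12_000), (15_000, 20_000)]),
            make_gene("gB", "chr1", 50_000, 60_000, "-"),
        ]
        return genes, GeneIndex(genes, {"chr1": 200_000})

    def test_upstream_center_is_promoter(self):
        genes, idx = self.make_index()
        ann = classify_peak(make_peak("chr1", 9_400, 9_600), idx)  # center 9500
        assert ann.category is Category.PROMOTER_TSS
        assert ann.assigned_gene == "gA"
        assert ann.distance_to_tss == -500  # upstream is negative

    def test_center_in_exon(self):
        genes, idx = self.make_index()
        ann = classify_peak(make_peak("chr1", 11_400, 11_600), idx)
        assert ann.category is Category.EXON and ann.assigned_gene == "gA"

    def test_center_in_intron(self):
        genes, idx = self.make_index()
        ann = classify_peak(make_peak("chr1", 13_000, 13_100), idx)
        assert ann.category is Category.INTRON

    def test_far_center_intergenic_with_nearest_gene(self):
        genes, idx = self.make_index()
        ann = classify_peak(make_peak("chr1", 110_000, 110_100), idx)
        assert ann.category is Category.INTERGENIC
        # brute-force nearest TSS: gA tss=10000 (d=100050), gB tss=59999 (d=50051)
        assert ann.assigned_gene == "gB"

    def test_geneless_chromosome(self):
        genes, idx = self.make_index()
        ann = classify_peak(make_peak("chr9", 100, 200), idx)
        assert ann.category is Category.INTERGENIC
        assert ann.assigned_gene is None

    def test_promoter_beats_exon_of_other_gene(self):
        # gC's promoter window overlaps gD's exon: promoter wins
        genes = [
            make_gene("gC", "chr1", 30_000, 40_000, "+"),
            make_gene("gD", "chr1", 20_000, 29_900, "+"),
        ]
        idx = GeneIndex(genes)
        ann = classify_peak(make_peak("chr1", 29_500, 29_700), idx)  # center 29600
        assert ann.category is Category.PROMOTER_TSS
        assert ann.assigned_gene == "gC"

    def test_every_peak_gets_exactly_one_category(self, rng):
        genes, idx = self.make_index()
        peaks = [
            make_peak("chr1", int(s), int(s) + 100)
            for s in rng.integers(0, 199_000, size=300)
        ]
        anns = annotate_peaks(peaks, idx)
        assert len(anns) == len(peaks)
        assert all(isinstance(a.category, Category) for a in anns)

    def test_translation_invariance(self, rng):
        shift = 40_000
        genes = [
            make_gene("g1", "chr1", 10_000, 14_000, "+",
                      exons=[(10_000, 11_000), (13_000, 14_000)]),
            make_gene("g2", "chr1", 20_000, 26_000, "-"),
        ]
        shifted = [
            make_gene(g.gene_id, "chr1",
                      g.interval.start + shift, g.interval.end + shift,
                      g.strand,
                      exons=[(e.start + shift, e.end + shift)
                             for e in g.exon_union()])
            for g in genes
        ]
        idx, idx2 = GeneIndex(genes), GeneIndex(shifted)
        for s in rng.integers(2_000, 30_000, size=500):
            a = classify_peak(make_peak("chr1", int(s), int(s) + 50), idx)
            b = classify_peak(
                make_peak("chr1", int(s) + shift, int(s) + shift + 50), idx2
            )
            assert (a.category, a.assigned_gene) == (b.category, b.assigned_gene)


class TestOracle:
    def test_matches_per_base_painting_on_random_genomes(self):
        """Interval-tree classifier vs brute-force per-base painter."""
        rng = np.random.default_rng(0)
        for rep in range(3):
            cfg = SimulationConfig(
                seed=rep, n_chroms=1, chrom_len=100_000,
                n_genes=int(rng.integers(5, 31)),
                gene_min_len=1_000, gene_max_len=4_000, min_gap=0,
            )
            genes, sizes = simulate_annotation(cfg, np.random.default_rng(rep))
            painted = {c: paint_genome(genes, c, l) for c, l in sizes.items()}
            peaks = [
                make_peak("chr1", int(s), int(s) + int(l))
                for s, l in zip(
                    rng.integers(0, 95_000, size=400),
                    rng.integers(1, 3_000, size=400),
                )
            ]
            anns = annotate_peaks(peaks, genes, sizes)
            for p, a in zip(peaks, anns):
                cat, gid = oracle_classify(p, genes, painted)
                assert (cat, gid) == (a.category, a.assigned_gene)


class TestSummary:
    def test_count_and_length_proportions(self):
        genes = [make_gene("g", "chr1", 10_000, 20_000, "+")]
        idx = GeneIndex(genes)
        peaks = [
            make_peak("chr1", 9_500, 9_600),    # promoter, length 100
            make_peak("chr1", 9_700, 9_800),    # promoter, length 100
            make_peak("chr1", 90_000, 90_300),  # intergenic, length 300
            make_peak("chr1", 95_000, 95_300),  # intergenic, length 300
        ]
        s = summarize_annotation(annotate_peaks(peaks, idx))
        assert s.count_proportions[Category.PROMOTER_TSS] == 0.5
        assert s.length_proportions[Category.PROMOTER_TSS] == 0.25
        assert s.length_proportions[Category.INTERGENIC] == 0.75

    def test_single_peak_proportion_one(self):
        genes = [make_gene("g", "chr1", 10_000, 20_000, "+")]
        anns = annotate_peaks([make_peak("chr1", 9_500, 9_600)],
                              GeneIndex(genes))
        s = summarize_annotation(anns)
        assert s.count_proportions[Category.PROMOTER_TSS] == 1.0

    def test_proportions_sum_to_one(self, default_dataset):
        ds = default_dataset
        for mark, peaks in ds.peaks.items():
            s = summarize_annotation(
                annotate_peaks(peaks, ds.genes, ds.chrom_sizes)
            )
            assert abs(sum(s.count_proportions.values()) - 1.0) < 1e-9
            assert abs(sum(s.length_proportions.values()) - 1.0) < 1e-9

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_annotation([])
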
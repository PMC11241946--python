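"""Marine-specificity criteria, coverage rules and the exclusion cascade."""

import numpy as np
import pandas as pd
import pytest

import regmark.screen as scr
from regmark.model import CoverageTrack, ExpressionTable, GenomicInterval
from tests.conftest import make_gene, make_peak


def design_4x3():
    return scr.EcotypeExpressionDesign(
        {
            scr.MARINE_FW: ("mf1", "mf2", "mf3", "mf4"),
            scr.MARINE_SW: ("ms1", "ms2", "ms3", "ms4"),
            scr.STREAM_FW: ("sf1", "sf2", "sf3", "sf4"),
        }
    )




class TestCriteria:
    def test_fold_criterion_on_means(self):
        # marine FW mean 80 vs 8 x stream mean 9 = 72: passes
        df = pd.DataFrame(
            {"g1": [80, 80, 80, 80, 20, 20, 20, 20, 9, 9, 9, 9]}
        ).T
        df.columns = ["mf1", "mf2", "mf3", "mf4", "ms1", "ms2", "ms3", "ms4",
                      "sf1", "sf2", "sf3", "sf4"]
        flags = scr.flag_ecotype_specific(df, design_4x3())
        c1, c2, c3 = flags["g1"]
        assert c1 is True and c2 is True

    def test_min_tpm_criterion_strictly_above_10(self):
        rows = {
            "hi": [50, 50, 50, 50, 12, 15, 11, 40, 1, 1, 1, 1],
            "border": [50, 50, 50, 50, 10, 15, 11, 40, 1, 1, 1, 1],
        }
        df = pd.DataFrame(rows).T
        df.columns = ["mf1", "mf2", "mf3", "mf4", "ms1", "ms2", "ms3", "ms4",
                      "sf1", "sf2", "sf3", "sf4"]
        flags = scr.flag_ecotype_specific(df, design_4x3())
        assert flags["hi"][1] is True       # min 11 > 10
        assert flags["border"][1] is False  # min 10 is not above 10

    def test_zero_stream_mean_passes_when_marine_positive(self):
        df = pd.DataFrame(
            {"g1": [5, 5, 5, 5, 20, 20, 20, 20, 0, 0, 0, 0]}
        ).T
        df.columns = ["mf1", "mf2", "mf3", "mf4", "ms1", "ms2", "ms3", "ms4",
                      "sf1", "sf2", "sf3", "sf4"]
        flags = scr.flag_ecotype_specific(df, design_4x3())
        assert flags["g1"][0] is True

    def test_assembled_chromosome_criterion(self):
        df = pd.DataFrame(
            {"g1": [80] * 4 + [20] * 4 + [1] * 4,
             "g2": [80] * 4 + [20] * 4 + [1] * 4}
        ).T
        df.columns = ["mf1", "mf2", "mf3", "mf4", "ms1", "ms2", "ms3", "ms4",
                      "sf1", "sf2", "sf3", "sf4"]
        flags = scr.flag_ecotype_specific(
            df, design_4x3(), assembled_chroms={"chr1"},
            gene_chrom={"g1": "chr1", "g2": "scaffold_99"},
        )
        assert flags["g1"][2] is True and flags["g2"][2] is False

    def test_raising_fold_never_adds_passers(self, rng):
        df = pd.DataFrame(
            rng.lognormal(2, 1, size=(50, 12)),
            index=[f"g{i}" for i in range(50)],
            columns=["mf1", "mf2", "mf3", "mf4", "ms1", "ms2", "ms3", "ms4",
                     "sf1", "sf2", "sf3", "sf4"],
        )
        passers = []
        for fold in (2.0, 4.0, 8.0, 16.0):
            flags = scr.flag_ecotype_specific(df, design_4x3(), fold=fold)
            passers.append({g for g, f in flags.items() if f[0]})
        for small, big in zip(passers, passers[1:]):
            assert big <= small


class TestCoverageRules:
    def test_uniform_coverage_present(self):
        g = make_gene("g", "chr1", 1_000, 2_000)
        cov = CoverageTrack({"chr1": [(0, 10_000, 30.0)]})
        assert scr.gene_body_present(cov, g)

    def test_zero_coverage_absent(self):
        g = make_gene("g", "chr1", 1_000, 2_000)
        cov = CoverageTrack({"chr1": [(0, 10_000, 0.0)]})
        assert not scr.gene_body_present(cov, g)

    def test_forty_percent_covered_is_absent(self):
        g = make_gene("g", "chr1", 0, 1_000)
        cov = CoverageTrack({"chr1": [(0, 400, 10.0)]})
        assert not scr.gene_body_present(cov, g)  # 0.4 < 0.5

    def test_no_chromosome_data_errors(self):
        g = make_gene("g", "chr2", 0, 1_000)
        cov = CoverageTrack({"chr1": [(0, 400, 10.0)]})
        with pytest.raises(KeyError):
            scr.gene_body_present(cov, g)


class TestUpstreamMarks:
    def test_peak_spanning_tss_found(self):
        g = make_gene("g", "chr1", 20_000, 30_000, "+")
        region = scr.upstream_marks(
            g, [make_peak("chr1", 19_500, 20_500, mark="H3K4me3")]
        )
        assert region == GenomicInterval("chr1", 19_500, 20_500)

    def test_wrong_mark_ignored(self):
        g = make_gene("g", "chr1", 20_000, 30_000, "+")
        assert scr.upstream_marks(
            g, [make_peak("chr1", 19_000, 19_800, mark="H3K27me3")]
        ) is None

    def test_peak_beyond_search_distance_ignored(self):
        g = make_gene("g", "chr1", 40_000, 50_000, "+")
        assert scr.upstream_marks(
            g, [make_peak("chr1", 19_000, 19_800, mark="H3K4me1")],
            search=10_000,
        ) is None

    def test_minus_strand_upstream_is_rightward(self):
        g = make_gene("g", "chr1", 20_000, 30_000, "-")  # tss = 29_999
        assert scr.upstream_marks(
            g, [make_peak("chr1", 33_000, 33_600, mark="H3K4me1")]
        ) is not None
        assert scr.upstream_marks(
            g, [make_peak("chr1", 25_000, 26_000, mark="H3K4me1")]
        ) is None


class TestIndelDetection:
    def region(self):
        return GenomicInterval("chr1", 5_000, 6_000)

    def test_complete_stream_gap_called(self):
        marine = CoverageTrack({"chr1": [(0, 10_000, 30.0)]})
        stream = CoverageTrack({"chr1": [(0, 5_000, 30.0), (6_000, 10_000, 30.0)]})
        call = scr.detect_candidate_indel(self.region(), marine, stream)
        assert call.type is scr.IndelType.DELETION_IN_STREAM
        assert call.interval == self.region()

    def test_both_covered_no_call(self):
        cov = CoverageTrack({"chr1": [(0, 10_000, 30.0)]})
        assert scr.detect_candidate_indel(self.region(), cov, cov) is None

    def test_85_percent_gap_reported_with_gap_interval(self):
        marine = CoverageTrack({"chr1": [(0, 10_000, 30.0)]})
        stream = CoverageTrack(
            {"chr1": [(0, 5_000, 30.0), (5_850, 10_000, 30.0)]}
        )  # gap 5000-5850 = 85% of the region
        call = scr.detect_candidate_indel(self.region(), marine, stream)
        assert call is not None
        assert call.interval == GenomicInterval("chr1", 5_000, 5_850)

    def test_marine_gap_blocks_call(self):
        gap = CoverageTrack({"chr1": [(0, 5_000, 30.0), (6_000, 10_000, 30.0)]})
        assert scr.detect_candidate_indel(self.region(), gap, gap) is None


class TestCascade:
    def _scenario(self, seed=0):
        from regmark.simulate import (
            SimulationConfig, simulate_annotation, simulate_peaks,
            simulate_screen_scenario,
        )

        cfg = SimulationConfig(
            seed=seed, n_chroms=2, chrom_len=1_000_000, n_genes=120,
            peak_counts={"H3K4me1": 30, "H3K4me3": 30},
        )
        rng = np.random.default_rng(seed)
        genes, sizes = simulate_annotation(cfg, rng)
        peaks, _ = simulate_peaks(cfg, genes, sizes, rng)
        scen = simulate_screen_scenario(cfg, genes, peaks, sizes, rng)
        return genes, sizes, scen

    def test_planted_dataset_recovered_exactly(self):
        genes, sizes, scen = self._scenario(seed=5)
        result = scr.run_cascade(
            scen.expr, scen.design, genes, scen.marine_cov, scen.stream_cov,
            scen.peaks, assembled_chroms=set(sizes),
        )
        assert result.candidates_with_indel() == set(scen.truth["deletions"])
        assert set(
            r.gene_id
            for r in result.by_disposition(
                scr.Disposition.EXCLUDED_MARINE_GENEBODY_ABSENT)
        ) == set(scen.truth["marine_absent"])
        assert set(
            r.gene_id
            for r in result.by_disposition(scr.Disposition.NO_UPSTREAM_MARKS)
        ) == set(scen.truth["unmarked"])

    def test_stage_counts_sum_to_criteria_passers(self):
        genes, sizes, scen = self._scenario(seed=6)
        result = scr.run_cascade(
            scen.expr, scen.design, genes, scen.marine_cov, scen.stream_cov,
            scen.peaks, assembled_chroms=set(sizes),
        )
        counts = result.stage_counts
        assert counts["criteria_passed"] == sum(
            counts[d.value] for d in scr.Disposition
        )
        assert counts["criteria_passed"] == sum(
            1 for r in result.records if r.passed
        )

    def test_marked_intact_gene_is_candidate_without_indel(self):
        g = make_gene("g1", "chr1", 20_000, 30_000, "+")
        tx = {"g1.t1": "g1"}
        tpm = pd.DataFrame(
            {s: [100.0] for s in ("mf1", "mf2", "mf3", "mf4")}
            | {s: [30.0] for s in ("ms1", "ms2", "ms3", "ms4")}
            | {s: [0.5] for s in ("sf1", "sf2", "sf3", "sf4")},
            index=["g1.t1"],
        )
        expr = ExpressionTable(tpm, tx)
        cov = CoverageTrack({"chr1": [(0, 50_000, 30.0)]})
        result = scr.run_cascade(
            expr, design_4x3(), [g], cov, cov,
            [make_peak("chr1", 17_000, 17_900, mark="H3K4me1")],
            assembled_chroms={"chr1"},
        )
        (rec,) = [r for r in result.records if r.passed]
        assert rec.disposition is scr.Disposition.CANDIDATE_NO_INDEL
        assert rec.candidate_region is not None

    def test_no_passers_empty_cascade(self):
        g = make_gene("g1", "chr1", 20_000, 30_000, "+")
        tpm = pd.DataFrame(
            {s: [1.0] for s in ("mf1", "mf2", "mf3", "mf4", "ms1", "ms2",
                                "ms3", "ms4", "sf1", "sf2", "sf3", "sf4")},
            index=["g1.t1"],
        )
        expr = ExpressionTable(tpm, {"g1.t1": "g1"})
        cov = CoverageTrack({"chr1": [(0, 50_000, 30.0)]})
        result = scr.run_cascade(expr, design_4x3(), [g], cov, cov, [],
                                 assembled_chroms={"chr1"})
        assert result.stage_counts["criteria_passed"] == 0
        assert all(r.disposition is None for r in result.records)
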
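"""Gene-category classification and mark-expression / mark-dN/dS tests."""

import math
from itertools import combinations

import numpy as np
import pytest

import regmark.association as assoc
from regmark.annotate import GeneIndex, annotate_peaks
from regmark.association import GeneCategory
from regmark.model import ExpressionTable
from tests.conftest import make_gene, make_peak

import pandas as pd


def records_from(values_by_cat, dnds_by_cat=None):
    out = []
    i = 0
    for cat, vals in values_by_cat.items():
        for j, v in enumerate(vals):
            d = dnds_by_cat[cat][j] if dnds_by_cat else None
            out.append(
                assoc.GeneAssociationRecord(f"g{i}", cat, v, dnds=d)
            )
            i += 1
    return out


class TestAggregation:
    def test_isoform_sum(self):
        tpm = pd.DataFrame({"s1": [3.0, 4.0, 5.0]}, index=["t1", "t2", "t3"])
        expr = ExpressionTable(tpm, {"t1": "g1", "t2": "g1", "t3": "g2"})
        agg = assoc.aggregate_isoform_tpm(expr, "s1")
        assert agg["g1"] == 7.0 and agg["g2"] == 5.0

    def test_unknown_sample(self):
        expr = ExpressionTable(pd.DataFrame({"s1": [1.0]}, index=["t1"]),
                               {"t1": "g1"})
        with pytest.raises(KeyError):
            assoc.aggregate_isoform_tpm(expr, "nope")


class TestClassifyGenes:
    def setup_method(self):
        self.genes = [
            make_gene("g1", "chr1", 10_000, 20_000, "+"),
            make_gene("g2", "chr1", 50_000, 60_000, "+"),
            make_gene("g3", "chr1", 90_000, 95_000, "+"),
            make_gene("g4", "chr2", 10_000, 20_000, "+"),
        ]
        self.idx = GeneIndex(self.genes)

    def test_three_way_partition(self):
        peaks = [
            make_peak("chr1", 9_500, 9_600),     # promoter of g1
            make_peak("chr1", 30_000, 30_100),   # intergenic, nearest g1 or g2
            make_peak("chr1", 70_000, 70_100),   # intergenic
        ]
        anns = annotate_peaks(peaks, self.idx)
        cats = assoc.classify_genes(anns, self.genes)
        # genic peak dominates any intergenic assignment
        assert cats["g1"] == GeneCategory.GENE
        assert GeneCategory.INTERGENIC in (cats["g2"], cats["g3"])
        # chr2 has no peaks at all: g4 excluded, not NO_PEAKS
        assert "g4" not in cats
        cats_all = assoc.classify_genes(anns, self.genes,
                                        restrict_to_annotated_chroms=False)
        assert cats_all["g4"] == GeneCategory.NO_PEAKS
        # partition covers every gene on annotated chromosomes
        assert set(cats) == {"g1", "g2", "g3"}

    def test_gene_without_peaks_is_no_peaks(self):
        peaks = [make_peak("chr1", 9_500, 9_600)]
        cats = assoc.classify_genes(annotate_peaks(peaks, self.idx), self.genes)
        assert cats["g3"] == GeneCategory.NO_PEAKS


class TestRankSum:
    def test_complete_separation_3v3_exact(self):
        """3-vs-3 complete separation: exact two-sided P = 2/20 = 0.1,
        verified by enumerating all C(6,3) = 20 rank assignments."""
        gene_vals = [11.0, 21.0, 31.0]
        nopk_vals = [2.0, 2.0, 2.0]
        # independent enumeration oracle on the observed values
        pooled = gene_vals + nopk_vals
        obs_u = sum(g > n for g in gene_vals for n in nopk_vals)
        count_ge = count_le = total = 0
        for pick in combinations(range(6), 3):
            a = [pooled[i] for i in pick]
            b = [pooled[i] for i in range(6) if i not in pick]
            u = sum(x > y for x in a for y in b) + 0.5 * sum(
                x == y for x in a for y in b
            )
            total += 1
            count_ge += u >= obs_u
            count_le += u <= obs_u
        expected_p = 2 * min(count_ge, count_le) / total
        assert expected_p == pytest.approx(0.1)

        records = records_from(
            {GeneCategory.GENE: gene_vals, GeneCategory.NO_PEAKS: nopk_vals}
        )
        comp = assoc.compare_expression(records)
        assert comp.p_value(GeneCategory.GENE, GeneCategory.NO_PEAKS) == \
            pytest.approx(expected_p)
        assert comp.median[GeneCategory.GENE] > comp.median[GeneCategory.NO_PEAKS]

    def test_all_tied_degenerate_p_is_one(self):
        records = records_from(
            {GeneCategory.GENE: [2.0] * 5, GeneCategory.NO_PEAKS: [2.0] * 5}
        )
        comp = assoc.compare_expression(records)
        assert comp.p_value(GeneCategory.GENE, GeneCategory.NO_PEAKS) == 1.0

    def test_rank_p_invariant_under_monotone_transform(self, rng):
        tpm_gene = rng.lognormal(2, 1, size=40)
        tpm_nopk = rng.lognormal(1, 1, size=40)
        raw = records_from(
            {GeneCategory.GENE: list(tpm_gene),
             GeneCategory.NO_PEAKS: list(tpm_nopk)}
        )
        # compare_expression works on ln(TPM+1); rank tests are invariant to
        # the monotone transform, so P computed on raw TPM must match
        from scipy.stats import mannwhitneyu

        p_raw = mannwhitneyu(tpm_gene, tpm_nopk, alternative="two-sided",
                             method="exact").pvalue
        comp = assoc.compare_expression(raw)
        assert comp.p_value(GeneCategory.GENE, GeneCategory.NO_PEAKS) == \
            pytest.approx(p_raw)

    def test_planted_shift_detected(self, rng):
        gene = list(np.expm1(rng.normal(2.5, 1.0, size=500)))
        nopk = list(np.expm1(rng.normal(1.5, 1.0, size=500)))
        records = records_from(
            {GeneCategory.GENE: gene, GeneCategory.NO_PEAKS: nopk}
        )
        comp = assoc.compare_expression(records)
        assert comp.p_value(GeneCategory.GENE, GeneCategory.NO_PEAKS) < 1e-3

    def test_single_category_rejected(self):
        records = records_from({GeneCategory.GENE: [1.0, 2.0]})
        with pytest.raises(ValueError):
            assoc.compare_expression(records)


class TestDnds:
    def test_filter_threshold_inclusive(self):
        filtered = assoc.filter_dnds({"g1": 0.2, "g2": 120.0, "g3": 99.0})
        assert filtered == {"g1": 0.2}

    def test_filter_empty(self):
        assert assoc.filter_dnds({}) == {}

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            assoc.filter_dnds({"g1": -0.1})

    def test_planted_lower_dnds_in_marked_genes(self, rng):
        dnds_gene = list(rng.lognormal(-1.5, 0.4, size=300))
        dnds_nopk = list(rng.lognormal(-0.8, 0.4, size=300))
        records = records_from(
            {GeneCategory.GENE: [1.0] * 300, GeneCategory.NO_PEAKS: [1.0] * 300},
            {GeneCategory.GENE: dnds_gene, GeneCategory.NO_PEAKS: dnds_nopk},
        )
        comp = assoc.compare_dnds(records)
        assert comp.median[GeneCategory.GENE] < comp.median[GeneCategory.NO_PEAKS]
        assert comp.p_value(GeneCategory.GENE, GeneCategory.NO_PEAKS) < 1e-3

    def test_missing_dnds_dropped(self):
        records = records_from(
            {GeneCategory.GENE: [1.0, 2.0, 3.0],
             GeneCategory.NO_PEAKS: [1.0, 2.0, 3.0]},
            {GeneCategory.GENE: [0.1, None, 0.3],
             GeneCategory.NO_PEAKS: [0.2, 0.4, None]},
        )
        comp = assoc.compare_dnds(records)
        assert comp.n[GeneCategory.GENE] == 2
        assert comp.n[GeneCategory.NO_PEAKS] == 2


class TestSpearman:
    def test_perfectly_monotone(self):
        records = [
            assoc.GeneAssociationRecord(f"g{i}", GeneCategory.GENE,
                                        float(i), dnds=float(i) * 0.1)
            for i in range(1, 6)
        ]
        rho, _ = assoc.correlate_expression_dnds(records)
        assert rho == pytest.approx(1.0)

    def test_perfectly_anti_monotone(self):
        records = [
            assoc.GeneAssociationRecord(f"g{i}", GeneCategory.GENE,
                                        float(i), dnds=1.0 / i)
            for i in range(1, 6)
        ]
        rho, _ = assoc.correlate_expression_dnds(records)
        assert rho == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        records = [
            assoc.GeneAssociationRecord(f"g{i}", GeneCategory.GENE,
                                        1.0, dnds=float(i))
            for i in range(5)
        ]
        with pytest.raises(ValueError):
            assoc.correlate_expression_dnds(records)

    def test_negative_coupling_generator(self):
        """dN/dS drawn with a negative log-linear coupling to expression
        gives rho < 0 in nearly all seeds."""
        neg = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            log_tpm = rng.normal(1.5, 1.0, size=200)
            dnds = np.exp(-0.5 - 0.3 * log_tpm + rng.normal(0, 0.5, 200))
            records = [
                assoc.GeneAssociationRecord(
                    f"g{i}", GeneCategory.GENE,
                    float(np.expm1(max(v, 0))), dnds=float(d)
                )
                for i, (v, d) in enumerate(zip(log_tpm, dnds))
            ]
            rho, _ = assoc.correlate_expression_dnds(records)
            neg += rho < 0
        assert neg >= 38  # >= 95% of seeds
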
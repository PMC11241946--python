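# regmark

Downstream analysis of histone-modification (CUT&Tag) and open-chromatin
(ATAC-seq) peak calls for two-ecotype genomes: peak annotation, association
of marks with gene expression and protein evolution, windowed nucleotide
diversity, sample clustering, and a screen for candidate *cis*-regulatory
indels. It is written for population/evolutionary genomicists who have
peaks (BED/broadPeak), gene models (GFF3/GTF), expression tables (TPM),
two-population genotypes (VCF) and whole-genome coverage (bedGraph), and
want the connecting statistics reproducible rather than ad hoc.

A synthetic-data generator (`regmark.simulate`) produces complete datasets
with planted effects and truth tables, so every stage is testable without
any sequencing data.

## What it computes

**Peak annotation.** Each peak is classified by its center base into
promoter/TSS (−1 kb to +100 bp of the TSS), TTS (−100 bp to +1 kb), exon,
intron, or intergenic (attributed to the closest gene by center-to-TSS
distance), with category proportions by peak count and by summed length.

**Mark–expression / mark–dN/dS association.** Per mark, genes partition
into *Gene* (a peak at the promoter/exon/intron/TTS), *Intergenic* (only
nearby intergenic peaks) and *No peaks*; ln(TPM+1) — with TPM summed over
isoforms — and ln(dN/dS+1) (genes with dN/dS ≥ 99 excluded) are compared
across groups by the two-sided Wilcoxon rank-sum test, and TPM is
correlated with dN/dS by Spearman's ρ.

**Windowed diversity.** Per site with m called alleles, c alternate:
π = 2c(m−c)/(m(m−1)); between populations D_XY = p₁(1−p₂) + p₂(1−p₁).
Sites are summed in non-overlapping 10-kb windows and divided by the
accessible length; windows with <10 SNPs are dropped; windows overlapping
peaks (≥1 bp) are compared against the rest by rank-sum tests.

**Sample clustering.** Fragment counts in 5,000-bp genome bins, pairwise
Spearman ρ, average-linkage dendrogram on 1−ρ (Newick output).

**Candidate screen.** Marine-specific genes (marine-FW mean TPM > 8× the
stream-FW mean; marine-SW minimum TPM > 10; assembled chromosome) run an
exclusion cascade — gene body absent in marine, then in stream, then no
upstream H3K4me1/H3K4me3 mark within 10 kb — and a stream-specific coverage
gap over the marked region calls a candidate *cis*-regulatory deletion.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
from regmark import (SimulationConfig, generate, ScreenConfig, run_cascade)

ds = generate(SimulationConfig(seed=1))      # synthetic two-ecotype study
scen = ds.screen
result = run_cascade(scen.expr, scen.design, ds.genes, scen.marine_cov,
                     scen.stream_cov, scen.peaks, ScreenConfig(),
                     assembled_chroms=set(ds.chrom_sizes))
print(result.stage_counts)
```

prints

```
{'criteria_passed': 8, 'EXCLUDED_MARINE_GENEBODY_ABSENT': 2,
 'EXCLUDED_STREAM_GENEBODY_ABSENT': 2, 'NO_UPSTREAM_MARKS': 1,
 'CANDIDATE_WITH_INDEL': 3, 'CANDIDATE_NO_INDEL': 0}
```

Eight genes pass the marine-specificity criteria; four are excluded because
their gene body is simply missing from one ecotype's genome (expression
specificity without regulation), one lacks upstream active marks, and the
remaining three — exactly the planted ones — carry a stream deletion of the
marked upstream region, e.g.
`g00052: DELETION_IN_STREAM chr1:427845-428747 (902 bp)`.

The same dataset drives the other stages (`examples/` has one script per
capability, with commentary). For instance the diversity stage
(`examples/04_windowed_diversity.py`) retains 100 windows and reports
elevated variation inside peaks — median π 2.11×10⁻³ vs 1.35×10⁻³
(P = 5.0×10⁻³) and median D_XY 3.44×10⁻³ vs 2.35×10⁻³ (P = 1.2×10⁻⁵) —
reflecting the generator's doubled polymorphism rate inside peaks, and the
association stage (`examples/03_expression_association.py`) shows genes
with active marks above unmarked genes (median ln(TPM+1) 2.25 vs 0.94,
P = 8.0×10⁻³), H3K27me3-marked genes below them (1.13 vs 2.52,
P = 8.8×10⁻⁶), and Spearman ρ = −0.60 (P = 4.3×10⁻¹³) between TPM and
dN/dS.

A thin CLI mirrors the library: `regmark simulate | annotate | associate |
diversity | cluster | screen | run` (see `regmark --help`).

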
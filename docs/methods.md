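# Methods

`regmark` reimplements, as a tested library, the downstream analyses that
connect histone-modification and open-chromatin peak calls to gene
expression, protein evolution, nucleotide diversity, and candidate
*cis*-regulatory indels in a two-ecotype (marine/stream stickleback-style)
study design. This note records the models, the parameter choices, the
numerical conventions, and what the synthetic data generator does and does
not emulate.

## Coordinate conventions

All interval arithmetic is done in a single convention: 0-based, half-open
`[start, end)` on the forward reference strand. GFF3/GTF features (1-based
closed) and VCF positions (1-based) are converted once on ingest and never
again; BED, broadPeak and bedGraph pass through unchanged. Genes are
represented at gene level: the span is the union of the transcript spans,
the TSS is the strand-aware 5' end of that span and the TTS its 3' end.
Annotating against the gene-level span, rather than per isoform, matches the
downstream analyses, which all speak about "the (closest) gene".

## Peak annotation

Each peak is assigned one of five categories by the location of its center
base, `start + floor(length/2)`:

* **promoter/TSS** — within −1 kb to +100 bp of a TSS (strand-aware,
  both endpoints inclusive);
* **TTS** — within −100 bp to +1 kb of a TTS;
* **exon** — in the union of exons across the gene's isoforms;
* **intron** — in the gene span but not in any exon;
* **intergenic** — none of the above; the peak is attributed to the
  closest gene by unsigned center-to-TSS distance.

When a center falls into features of more than one gene, precedence is
promoter > TTS > exon > intron, then smaller |distance to TSS|, then gene
id. The precedence had to be chosen (a center can sit simultaneously in one
gene's promoter window and another's exon); promoter-first mirrors common
annotators, and the id tie-break makes annotation fully deterministic —
a property the test suite exploits by comparing the interval-tree
implementation against a brute-force per-base painter.

Category summaries report both peak counts and summed peak lengths (the
whole peak length is attributed to its center's category), each as
proportions that sum to 1.

## Mark–expression and mark–dN/dS association

For one mark and sample, genes partition into **GENE** (≥1 peak whose
center-category is promoter/exon/intron/TTS and whose assigned gene is this
gene), **INTERGENIC** (only nearest-gene intergenic peaks) and
**NO_PEAKS**. A gene with both genic and intergenic peaks is GENE. Genes on
chromosomes carrying no peaks at all are excluded rather than called
NO_PEAKS, so missing data is not mistaken for absence of marks (a flag
restores the naive behaviour).

Expression is gene-level TPM — the sum over the gene's isoforms — and
comparisons run on ln(TPM+1). Groups are compared pairwise with the
two-sided Wilcoxon rank-sum test: the exact null distribution when both
groups have ≤50 observations, the normal approximation with tie correction
above that. Two all-tied identical groups return P = 1 by convention. No
multiple-testing correction is applied across the three pairwise tests by
default (a flag enables Holm), matching how such panels are usually
reported.

dN/dS values arrive as a per-gene table; genes with dN/dS ≥ 99 are removed
before any analysis because the ratio explodes when dS approaches zero.
Group comparisons use ln(dN/dS+1); the expression–evolution coupling is
summarised by Spearman's rank correlation of TPM against dN/dS (two-sided),
which errors on constant input rather than returning an undefined rho.

## Windowed nucleotide diversity

Per site, with `m` called alleles of which `c` are the alternate,

* within-population: `pi = 2 c (m − c) / (m (m − 1))` — the probability
  that two alleles drawn without replacement differ;
* between populations: `D_XY = p1 (1 − p2) + p2 (1 − p1)` with
  `p_k = c_k / m_k`.

Missing genotypes reduce `m` at the site instead of dropping the site.
Sites are summed over non-overlapping 10-kb windows and divided by the
number of accessible sites `L` — the window length by default (the
"all-site" interpretation), or the callable-base count when an
accessibility mask is supplied. Windows with fewer than 10 SNPs are
excluded. The trailing partial window of each chromosome is kept with `L`
set to its true length and a `partial` flag, rather than silently
truncated. A window is "in peak" if it overlaps any peak by ≥1 bp
(configurable); windows inside and outside peaks are compared by the
two-sided rank-sum test on pi (for a chosen population — both are reported)
and on D_XY.

The implementation is vectorised over sites; its independent cross-check
(`regmark.evaluation`) enumerates all allele pairs per site and agrees to
1e-12.

## Coverage binning and sample clustering

Fragments are counted into 5,000-bp bins; a fragment increments every bin
it overlaps (difference-array accumulation, so counting is O(fragments)).
Samples are compared by Spearman correlation of their concatenated
genome-wide bin vectors — zero-inflated coverage makes rank correlation the
safer choice — and clustered by average-linkage agglomeration on distance
1 − rho. Samples are id-sorted before linkage so the dendrogram is
invariant to input order; a constant bin vector raises an error naming the
sample, since its rank correlation is undefined. The dendrogram serialises
to Newick.

## The candidate *cis*-regulatory screen

Marine-specific genes are flagged by three criteria on gene-level TPM:

1. mean TPM of the four freshwater-acclimated marine samples exceeds
   **8×** the mean of the four freshwater-acclimated stream samples
   (strict `>`; a zero stream mean passes whenever the marine mean is
   positive);
2. the minimum TPM of the four seawater-acclimated marine samples is
   strictly above **10**;
3. the gene lies on an assembled chromosome.

Passing genes run an exclusion cascade, in order: genes whose body is
absent from the marine genome, then from the stream genome, are excluded
(their expression specificity reflects presence/absence of the gene, not
regulation); the remainder require an H3K4me1 and/or H3K4me3 peak
intersecting the strand-aware window from 10 kb upstream of the TSS to
100 bp downstream; finally, a stream-specific coverage gap over the marked
region calls **CANDIDATE_WITH_INDEL**, otherwise **CANDIDATE_NO_INDEL**.
Stage counts are conserved: the five dispositions sum to the number of
criteria-passing genes.

The original determinations of "gene body absent" and "deleted region"
were made by eye from read pileups; this package formalises them as
coverage-fraction rules so they are reproducible: a gene body is present
when ≥50% of its span has depth ≥2; a deletion is called when ≥80% of the
candidate region is below depth 2 in the stream track while ≥80% is at or
above it in marine, and the maximal low-depth run is reported as the indel
interval. All three constants are configurable and are surrogates for
manual inspection, not calibrated detector thresholds. The 10-kb upstream
search default is a deliberate over-cover of the enhancer distances the
assay typically shows (a few kb); it, too, is configurable. Insertions in
the stream ecotype manifest in this representation only as coverage
anomalies; sequence reconstruction of inserted material is out of scope.

## Synthetic data generator

`regmark.simulate` produces a complete, mutually consistent dataset —
gene models, per-mark peaks, expression and dN/dS tables, two-population
genotypes, per-sample fragment sets, ecotype expression and two coverage
tracks — with truth tables for every planted effect. Defaults are fixed
once as the study-like conditions the analyses assume:

* genome: 2 chromosomes × 500 kb, 120 non-overlapping genes of 2–6 kb with
  1–5 exons and ≥2 kb gaps;
* peaks: ~50–100 per mark, 300–2,000 bp, with centers biased toward
  mark-typical categories (promoter-heavy H3K4me3/ATAC,
  intergenic-heavy H3K9me3/H3K27me3); each peak's truth category is
  verified against the classifier at generation time;
* expression: ln(TPM+1) ~ Normal(1.5, 1), +1.0 for genes with an active
  genic mark (H3K4me1/H3K4me3/ATAC), −1.0 for H3K27me3, truncated at 0;
  gene TPM split across isoforms by a Dirichlet draw;
* dN/dS: `exp(−0.5 − 0.3·ln(TPM+1) + Normal(0, 0.5))` — a negative
  log-linear coupling to expression;
* genotypes: every base polymorphic with probability 0.01 inside any peak
  and 0.005 outside; per-population alternate frequencies drawn
  independently from Beta(0.8, 0.8); diploid genotypes Binomial(2, p);
* fragments: 3 Dirichlet bin-intensity profiles × 2 replicate samples of
  20,000 fragments each;
* screen scenario: 12 ecotype samples (4 marine-freshwater, 4
  marine-seawater, 4 stream), 8 planted marine-specific genes of which 2
  lack the gene body in marine, 2 in stream, 1 lacks upstream marks, and 3
  carry a planted stream deletion of a marked upstream peak; coverage is
  piecewise-constant depth 30 with the planted gaps carved out.

Two constructions keep the scenario's truth table exact rather than merely
likely: background genes that would pass the marine-specificity criteria by
chance are redrawn, and background active peaks falling inside a planted
gene's upstream search window are dropped (planted genes are also spaced
≥30 kb apart where the genome allows, relaxing with a logged warning when
it does not). The generator is deterministic given its seed, to the byte,
across the full write-out.

Deliberate simplifications: sites are independent (no linkage
disequilibrium), so the generator is unsuitable for LD-based statistics;
expression noise is log-normal (uncritical for the rank-based tests
downstream); coverage has no sampling noise; fragments have fixed length
and no size distribution; no read-level (FASTQ) simulation. Passing tests
on these data demonstrate correctness of the statistical machinery and of
the planted-effect logic, not robustness to alignment artefacts, batch
effects or LD structure in real data.

## Problem sizes used in tests and the acceptance script

The oracle and recovery experiments run at the following scales, chosen so
the whole suite completes in about a minute while keeping each check
well-powered: 20 random genomes × 1,000 peaks for the annotation oracle; 50
random matrices (≤10 diploids/population, ≤500 sites, 5% missing) for the
diversity oracle; 100 replicates of 500+500 genes for expression-shift
recovery; one 6-Mb genome (300 windows per overlap group) for diversity
elevation plus 200 replicates of 50+50 windows for the type-I rate; 20
seeds × 1,000 genes for the screen closed loop; 20 seeds of 3×2 fragment
samples for clustering; 50 seeds for the write/re-parse round trip.

## Numerical and degenerate-input conventions

* Rank-sum: exact method ≤50 per group, asymptotic + tie correction above;
  all-tied identical groups → P = 1; an empty category skips its pairs with
  a warning; fewer than two non-empty categories is an error.
* Spearman rho on a constant vector: error, not NaN.
* `site_pi` needs ≥2 called alleles, `site_dxy` ≥1 per population; failing
  sites are skipped and counted, not fatal.
* Peaks extending past a chromosome end are clipped in binning with a
  warning; a start ≥ end record is a parse error with its line number.
* Multi-allelic and non-SNP VCF records are skipped and counted, not split
  into biallelic records.
* Candidate regions shorter than 50 bp are still evaluated, with a warning.

## Known limitations

The screen's coverage rules are surrogates for manual pileup inspection and
have no false-positive model; on real data their thresholds interact with
mappability and depth-of-coverage variation that the generator does not
emulate. The peak-overlap diversity comparison treats windows as
exchangeable, ignoring autocorrelation along the chromosome (absent by
construction in the generator, present in real data). Per-isoform
annotation, F_ST, phasing, peak calling, genotype calling and dN/dS
estimation are out of scope; the package consumes the corresponding
standard file formats instead.
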
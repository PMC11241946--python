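"""Independent oracles and recovery-rate experiments.

The oracles here deliberately use a different algorithm from the production
code paths they check: the annotation oracle paints every base of a small
genome by scanning all genes per base, and the diversity oracles enumerate
allele pairs per site.  The experiment functions quantify how reliably the
pipeline recovers effects planted by :mod:`regmark.simulate` over many
seeded replicates; they are used both by the test suite and by the
acceptance script.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np

from . import association as assoc
from . import clustering as clust
from . import diversity as div
from .annotate import Category, GeneIndex, annotate_peaks, peak_center
from .model import GeneModel, GenomicInterval, GenotypeMatrix, Peak
from .screen import ScreenConfig, run_cascade
from .simulate import (
    SimulationConfig,
    generate,
    simulate_annotation,
    simulate_expression,
    simulate_fragments,
    simulate_genotypes,
    simulate_peaks,
    simulate_screen_scenario,
)

_RANK = {
    Category.PROMOTER_TSS: 0,
    Category.TTS: 1,
    Category.EXON: 2,
    Category.INTRON: 3,
}


# --------------------------------------------------------------------------
# oracles
# --------------------------------------------------------------------------

def paint_genome(
    genes: Sequence[GeneModel], chrom: str, length: int,
    index: Optional[GeneIndex] = None,
) -> tuple[list[Optional[Category]], list[Optional[str]]]:
    """Brute-force per-base classification of one chromosome.

    For every base, every gene is tested independently (promoter window,
    TTS window, exon union, span) and the winning (precedence, |distance to
    TSS|, gene id) triple is kept.  Bases outside all gene features stay
    None (intergenic).  Vectorised per gene but still a full per-base
    painting, independent of the interval-tree classifier.
    """
    rank = np.full(length, 99, dtype=np.int8)
    dist = np.full(length, np.iinfo(np.int64).max, dtype=np.int64)
    gene_at = np.full(length, -1, dtype=np.int64)
    chrom_genes = [(i, g) for i, g in enumerate(genes) if g.chrom == chrom]
    for gi, g in chrom_genes:
        tss = g.tss
        if g.strand == "+":
            prom = (tss - 1000, tss + 101)
            ttsw = (g.tts - 100, g.tts + 1001)
        else:
            prom = (tss - 100, tss + 1001)
            ttsw = (g.tts - 1000, g.tts + 101)
        per_gene_rank = np.full(length, 99, dtype=np.int8)
        span = g.interval
        per_gene_rank[max(span.start, 0):min(span.end, length)] = _RANK[Category.INTRON]
        for e in g.exon_union():
            per_gene_rank[max(e.start, 0):min(e.end, length)] = _RANK[Category.EXON]
        per_gene_rank[max(ttsw[0], 0):min(ttsw[1], length)] = _RANK[Category.TTS]
        per_gene_rank[max(prom[0], 0):min(prom[1], length)] = _RANK[Category.PROMOTER_TSS]
        pos = np.arange(length)
        gdist = np.abs(pos - tss)
        better = (per_gene_rank < rank) | (
            (per_gene_rank == rank) & (gdist < dist)
        )
        # equal rank and distance: smaller gene id wins; genes are scanned in
        # input order, so only strictly better entries overwrite, and ties on
        # (rank, dist) are resolved by comparing ids explicitly
        tie = (per_gene_rank == rank) & (gdist == dist) & (gene_at >= 0)
        if np.any(tie):
            ids = np.array([genes[i].gene_id if i >= 0 else "" for i in gene_at])
            tie &= g.gene_id < ids
            better |= tie
        upd = better & (per_gene_rank < 99)
        rank[upd] = per_gene_rank[upd]
        dist[upd] = gdist[upd]
        gene_at[upd] = gi
    inv = {v: k for k, v in _RANK.items()}
    cats = [inv.get(int(r)) for r in rank]
    gids = [genes[i].gene_id if i >= 0 else None for i in gene_at]
    return cats, gids


def oracle_classify(
    peak: Peak, genes: Sequence[GeneModel],
    painted: Mapping[str, tuple[list, list]],
) -> tuple[Category, Optional[str]]:
    """Look a peak's center up in a per-base painting; intergenic centers
    get the nearest gene by unsigned center-to-TSS distance (id-tie-broken)."""
    center = peak_center(peak)
    cats, gids = painted[peak.chrom]
    cat = cats[center]
    if cat is not None:
        return cat, gids[center]
    best = None
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        key = (abs(g.tss - center), g.gene_id)
        if best is None or key < best:
            best = key
    return Category.INTERGENIC, (best[1] if best else None)


def annotation_oracle_agreement(
    n_genomes: int = 20, n_peaks: int = 1000, seed: int = 0
) -> float:
    """Fraction of (category, gene) calls where the interval-tree classifier
    agrees with the per-base painting oracle over random small genomes."""
    agree = total = 0
    for rep in range(n_genomes):
        rng = np.random.default_rng((seed, rep))
        cfg = SimulationConfig(
            seed=seed + rep, n_chroms=1, chrom_len=100_000,
            n_genes=int(rng.integers(5, 31)), gene_min_len=1_000,
            gene_max_len=4_000, min_gap=0,
        )
        genes, chrom_sizes = simulate_annotation(cfg, rng)
        painted = {
            c: paint_genome(genes, c, l) for c, l in chrom_sizes.items()
        }
        chroms = list(chrom_sizes)
        peaks = []
        for _ in range(n_peaks):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            length = int(rng.integers(1, 3_000))
            start = int(rng.integers(0, chrom_sizes[chrom] - length))
            peaks.append(
                Peak(GenomicInterval(chrom, start, start + length),
                     "H3K4me1", "oracle")
            )
        anns = annotate_peaks(peaks, genes, chrom_sizes)
        for p, a in zip(peaks, anns):
            cat, gid = oracle_classify(p, genes, painted)
            agree += int(cat == a.category and gid == a.assigned_gene)
            total += 1
    return agree / total


def pairwise_pi(genotypes: np.ndarray) -> float:
    """Per-site pi by enumerating all within-population allele pairs.

    ``genotypes``: alt-allele counts per diploid sample (-1 = missing).
    """
    alleles: list[int] = []
    for g in genotypes:
        if g >= 0:
            alleles.extend([1] * int(g) + [0] * (2 - int(g)))
    n = len(alleles)
    if n < 2:
        raise ValueError("fewer than two called alleles")
    diff = pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            pairs += 1
            diff += alleles[i] != alleles[j]
    return diff / pairs


def pairwise_dxy(g1: np.ndarray, g2: np.ndarray) -> float:
    """Per-site D_XY by enumerating all between-population allele pairs."""
    def expand(gs):
        out = []
        for g in gs:
            if g >= 0:
                out.extend([1] * int(g) + [0] * (2 - int(g)))
        return out

    a1, a2 = expand(g1), expand(g2)
    if not a1 or not a2:
        raise ValueError("a population has no called alleles")
    diff = sum(x != y for x in a1 for y in a2)
    return diff / (len(a1) * len(a2))


def window_oracle(
    gm: GenotypeMatrix, chrom_lengths: Mapping[str, int],
    window: int = 10_000, min_snps: int = 10,
) -> list[dict]:
    """Brute-force windowed pi/D_XY from per-site pair enumeration."""
    pops = gm.population_names()
    out = []
    for chrom, length in chrom_lengths.items():
        if chrom not in gm.data:
            continue
        pos, geno = gm.data[chrom]
        idx1 = gm.sample_indices(pops[0])
        idx2 = gm.sample_indices(pops[1])
        n_windows = int(np.ceil(length / window))
        for w in range(n_windows):
            lo, hi = w * window, min((w + 1) * window, length)
            sel = (pos >= lo) & (pos < hi)
            if int(sel.sum()) < min_snps:
                continue
            L = hi - lo
            pi1 = pi2 = dxy = 0.0
            for i in np.flatnonzero(sel):
                row = geno[i]
                try:
                    pi1 += pairwise_pi(row[idx1])
                except ValueError:
                    pass
                try:
                    pi2 += pairwise_pi(row[idx2])
                except ValueError:
                    pass
                try:
                    dxy += pairwise_dxy(row[idx1], row[idx2])
                except ValueError:
                    pass
            out.append(
                {"chrom": chrom, "start": lo, "end": hi,
                 "pi": {pops[0]: pi1 / L, pops[1]: pi2 / L}, "dxy": dxy / L}
            )
    return out


def diversity_oracle_max_error(
    n_matrices: int = 50, seed: int = 0
) -> float:
    """Max |windowed statistic - pair-enumeration oracle| over random small
    genotype matrices (pi for both populations and D_XY)."""
    worst = 0.0
    for rep in range(n_matrices):
        rng = np.random.default_rng((seed, rep))
        n_per_pop = int(rng.integers(2, 11))
        n_sites = int(rng.integers(30, 501))
        length = 100_000
        pos = np.sort(
            rng.choice(length, size=n_sites, replace=False)
        ).astype(np.int64)
        geno = rng.integers(0, 3, size=(n_sites, 2 * n_per_pop)).astype(np.int8)
        miss = rng.random(geno.shape) < 0.05
        geno[miss] = -1
        samples = [f"a{i}" for i in range(n_per_pop)] + [
            f"b{i}" for i in range(n_per_pop)
        ]
        pops = {s: ("p1" if s.startswith("a") else "p2") for s in samples}
        gm = GenotypeMatrix(samples, pops, {"chr1": (pos, geno)},
                            chrom_lengths={"chr1": length})
        windows = div.windowed_diversity(gm, window=10_000, min_snps=1)
        oracle = window_oracle(gm, {"chr1": length}, window=10_000, min_snps=1)
        assert len(windows) == len(oracle)
        for w, o in zip(windows, oracle):
            worst = max(
                worst,
                abs(w.pi["p1"] - o["pi"]["p1"]),
                abs(w.pi["p2"] - o["pi"]["p2"]),
                abs(w.dxy - o["dxy"]),
            )
    return worst


# --------------------------------------------------------------------------
# planted-effect recovery experiments
# --------------------------------------------------------------------------

def expression_effect_recovery(
    n_replicates: int = 100,
    n_per_class: int = 500,
    delta: float = 1.0,
    alpha: float = 1e-3,
    seed: int = 0,
) -> float:
    """Fraction of replicates where the planted active-mark expression shift
    yields GENE-vs-NO_PEAKS rank-sum P < alpha.

    Each replicate simulates a genome of ``2 * n_per_class`` genes, plants a
    promoter H3K4me3 peak on half of them, then runs the full annotate ->
    classify -> compare path.
    """
    hits = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng((seed, rep))
        n_genes = 2 * n_per_class
        cfg = SimulationConfig(
            seed=seed + rep, n_chroms=4, chrom_len=2_000_000,
            n_genes=n_genes, gene_min_len=2_000, gene_max_len=5_000,
            min_gap=500, delta_active=delta,
            peak_counts={"H3K4me3": 0},
        )
        genes, chrom_sizes = simulate_annotation(cfg, rng)
        marked = rng.choice(len(genes), size=n_per_class, replace=False)
        peaks = {
            "H3K4me3": [
                Peak(
                    GenomicInterval(
                        genes[i].chrom,
                        max(genes[i].tss - 200, 0),
                        genes[i].tss + 200,
                    ),
                    "H3K4me3", "sim",
                )
                for i in marked
            ]
        }
        expr, _dnds, _truth = simulate_expression(
            cfg, genes, peaks, chrom_sizes, rng, samples=("rep1",)
        )
        anns = annotate_peaks(peaks["H3K4me3"], genes, chrom_sizes)
        cats = assoc.classify_genes(anns, genes)
        records = assoc.build_records(cats, expr.gene_tpm("rep1"))
        comp = assoc.compare_expression(records)
        p = comp.p_value(assoc.GeneCategory.GENE, assoc.GeneCategory.NO_PEAKS)
        hits += int(p < alpha)
    return hits / n_replicates


def _diversity_replicate(theta_in, theta_out, genome_len, seed):
    """One two-population genotype simulation with peaks tiling alternating
    10-kb windows; returns the peak-overlap comparison."""
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig(seed=0, theta_in=theta_in, theta_out=theta_out,
                           chrom_len=max(genome_len, 100_000))
    chrom_sizes = {"chr1": genome_len}
    peaks = [
        Peak(GenomicInterval("chr1", s, s + 10_000), "H3K4me1", "sim")
        for s in range(0, genome_len - 10_000 + 1, 20_000)
    ]
    gm = simulate_genotypes(cfg, peaks, chrom_sizes, rng)
    windows = div.windowed_diversity(gm, chrom_sizes, window=10_000,
                                     min_snps=10)
    return div.compare_peak_overlap(windows, peaks)


def diversity_elevation_recovery(
    n_windows_per_group: int = 300,
    theta_out: float = 0.005,
    ratio: float = 2.0,
    seed: int = 0,
) -> tuple[float, float]:
    """(pi P-value, D_XY P-value) for one doubled-polymorphism genome with
    >= ``n_windows_per_group`` windows inside and outside peaks."""
    genome_len = 2 * n_windows_per_group * 10_000
    comp = _diversity_replicate(theta_out * ratio, theta_out, genome_len, (seed, 9999))
    assert comp.n_in >= n_windows_per_group * 0.9
    return comp.pi_p, comp.dxy_p


def diversity_type_i_error(
    n_replicates: int = 200,
    theta: float = 0.005,
    n_windows_per_group: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical rejection rate of the peak-overlap pi comparison when
    polymorphism is identical inside and outside peaks."""
    genome_len = 2 * n_windows_per_group * 10_000
    hits = 0
    for rep in range(n_replicates):
        comp = _diversity_replicate(theta, theta, genome_len, (seed, rep))
        hits += int(comp.pi_p < alpha)
    return hits / n_replicates


def screen_recovery_rate(
    n_seeds: int = 20, n_genes: int = 1000, seed: int = 0
) -> float:
    """Fraction of seeds where the cascade's CANDIDATE_WITH_INDEL set equals
    the planted deletion set exactly, on 1,000-gene scenarios."""
    exact = 0
    for rep in range(n_seeds):
        cfg = SimulationConfig(
            seed=seed + rep, n_chroms=4, chrom_len=2_000_000,
            n_genes=n_genes, gene_min_len=2_000, gene_max_len=4_000,
            min_gap=500,
            peak_counts={"H3K4me1": 40, "H3K4me3": 40},
        )
        rng = np.random.default_rng((seed, rep))
        genes, chrom_sizes = simulate_annotation(cfg, rng)
        peaks, _ = simulate_peaks(cfg, genes, chrom_sizes, rng)
        scenario = simulate_screen_scenario(cfg, genes, peaks, chrom_sizes, rng)
        result = run_cascade(
            scenario.expr, scenario.design, genes, scenario.marine_cov,
            scenario.stream_cov, scenario.peaks, ScreenConfig(),
            assembled_chroms=set(chrom_sizes),
        )
        exact += int(
            result.candidates_with_indel() == set(scenario.truth["deletions"])
        )
    return exact / n_seeds


def clustering_sibling_recovery(n_seeds: int = 20, seed: int = 0) -> float:
    """Fraction of seeds where every replicate pair from the same planted
    coverage profile merges as dendrogram siblings."""
    ok = 0
    for rep in range(n_seeds):
        cfg = SimulationConfig(seed=seed + rep, n_chroms=1,
                               chrom_len=500_000)
        rng = np.random.default_rng((seed, rep))
        chrom_sizes = {"chr1": cfg.chrom_len}
        fragments, truth = simulate_fragments(cfg, chrom_sizes, rng)
        covs = [
            clust.bin_fragments(frags, chrom_sizes, cfg.bin_size, sid)
            for sid, frags in sorted(fragments.items())
        ]
        cm = clust.correlation_matrix(covs)
        dend = clust.cluster_samples(cm)
        by_profile: dict[int, list[str]] = {}
        for sid, pi in truth.items():
            by_profile.setdefault(pi, []).append(sid)
        ok += int(all(
            dend.siblings(sids[0], sids[1]) for sids in by_profile.values()
        ))
    return ok / n_seeds


def roundtrip_success_rate(n_seeds: int = 50, seed: int = 0,
                           workdir: Optional[str] = None) -> float:
    """Fraction of seeds where a full synthetic dataset survives a write ->
    re-parse cycle with genes and peaks reproduced exactly and genotypes
    site-for-site identical."""
    import tempfile
    from pathlib import Path

    from . import io as gio

    ok = 0
    for rep in range(n_seeds):
        cfg = SimulationConfig(
            seed=seed + rep, n_chroms=2, chrom_len=120_000, n_genes=20,
            peak_counts={"H3K4me1": 10, "H3K4me3": 10, "H3K27me3": 5},
            theta_out=0.002, theta_in=0.004, n_samples_per_pop=4,
            fragments_per_sample=500, n_marine_specific=5,
            n_marine_absent=1, n_stream_absent=1, n_unmarked=1,
            n_deletions=2,
        )
        ds = generate(cfg)
        with tempfile.TemporaryDirectory(dir=workdir) as tmp:
            ds.write(tmp)
            tmp = Path(tmp)
            genes2 = gio.parse_gene_models(tmp / "genes.gff3")
            good = genes2 == ds.genes
            for mark, plist in ds.peaks.items():
                back = gio.parse_peaks(tmp / f"peaks_{mark}.bed", mark, "sim")
                good &= [p.interval for p in back] == [p.interval for p in plist]
            popmap = gio.parse_popmap(tmp / "popmap.tsv")
            gm2 = gio.parse_genotypes(tmp / "populations.vcf", popmap)
            for chrom in ds.genotypes.chroms:
                pos, geno = ds.genotypes.data[chrom]
                pos2, geno2 = gm2.data[chrom]
                good &= bool(
                    np.array_equal(pos, pos2) and np.array_equal(geno, geno2)
                )
            expr2 = gio.parse_expression(tmp / "tpm.tsv", tmp / "tx2gene.tsv")
            good &= bool(
                np.allclose(expr2.tpm.values, ds.expr.tpm.values, atol=1e-9)
            )
            cov2 = gio.parse_bedgraph(tmp / "stream.bedgraph")
            for chrom in ds.screen.stream_cov.chroms:
                a = ds.screen.stream_cov.runs[chrom]
                b = cov2.runs[chrom]
                good &= all(np.array_equal(x, y) for x, y in zip(a, b))
        ok += int(good)
    return ok / n_seeds
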
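"""Synthetic datasets with the statistical structure the analyses assume.

The generator emulates the study design end to end on a desk-scale genome:
gene models on a few short chromosomes; per-mark peak sets whose centers are
biased toward mark-typical categories (promoter-heavy H3K4me3,
intergenic-heavy H3K9me3); expression shifted up for genes carrying active
genic marks (H3K4me1/H3K4me3/ATAC) and down for H3K27me3; dN/dS negatively
coupled to expression; two-population genotypes with polymorphism elevated
inside peaks; binned fragment samples from planted coverage profiles; and a
marine/stream ecotype screen scenario with planted gene-body absences and
upstream cis-regulatory deletions.  Every planted effect is recorded in a
truth table so downstream recovery can be checked exactly.

Polymorphic sites are independent (no linkage) and coverage is piecewise
constant; both are deliberate simplifications adequate for rank-based and
coverage-fraction statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as gio
from .annotate import Category, GeneIndex, annotate_peaks, classify_peak
from .model import (
    CoverageTrack,
    ExpressionTable,
    GeneModel,
    GenomicInterval,
    GenotypeMatrix,
    Peak,
    Transcript,
    ACTIVE_MARKS,
)
from .screen import (
    MARINE_FW,
    MARINE_SW,
    STREAM_FW,
    EcotypeExpressionDesign,
)

logger = logging.getLogger(__name__)

_DEFAULT_PEAK_COUNTS = {
    "H3K4me1": 100,
    "H3K4me3": 100,
    "H3K27me3": 80,
    "H3K9me3": 50,
    "ATAC": 100,
}

# mark-typical center-category biases in the spirit of promoter-enriched
# active marks and heterochromatin-enriched repressive marks
_DEFAULT_BIAS = {
    "H3K4me1": {"PROMOTER_TSS": 0.25, "EXON": 0.15, "INTRON": 0.25,
                "TTS": 0.10, "INTERGENIC": 0.25},
    "H3K4me3": {"PROMOTER_TSS": 0.55, "EXON": 0.15, "INTRON": 0.10,
                "TTS": 0.05, "INTERGENIC": 0.15},
    "H3K27me3": {"PROMOTER_TSS": 0.15, "EXON": 0.10, "INTRON": 0.20,
                 "TTS": 0.10, "INTERGENIC": 0.45},
    "H3K9me3": {"PROMOTER_TSS": 0.05, "EXON": 0.05, "INTRON": 0.15,
                "TTS": 0.05, "INTERGENIC": 0.70},
    "ATAC": {"PROMOTER_TSS": 0.45, "EXON": 0.15, "INTRON": 0.15,
             "TTS": 0.05, "INTERGENIC": 0.20},
}


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the study-like conditions the
    downstream analyses assume (see docs/methods.md)."""

    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_len: int = 500_000
    n_genes: int = 120
    gene_min_len: int = 2_000
    gene_max_len: int = 6_000
    min_gap: int = 2_000
    # peaks
    peak_counts: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_PEAK_COUNTS))
    category_bias: dict[str, dict[str, float]] = field(
        default_factory=lambda: {m: dict(b) for m, b in _DEFAULT_BIAS.items()})
    peak_min_len: int = 300
    peak_max_len: int = 2_000
    # expression model on the ln(TPM+1) scale
    mu_log_tpm: float = 1.5
    sigma_log_tpm: float = 1.0
    delta_active: float = 1.0
    delta_repressive: float = 1.0
    # dN/dS model: dnds = exp(base - slope * ln(TPM+1) + noise)
    dnds_base: float = -0.5
    dnds_slope: float = 0.3
    dnds_noise: float = 0.5
    # diversity model
    theta_out: float = 0.005
    theta_in: float = 0.01
    n_samples_per_pop: int = 8
    beta_shape: float = 0.8
    missing_rate: float = 0.0
    # fragment / clustering model
    n_profiles: int = 3
    reps_per_profile: int = 2
    fragments_per_sample: int = 20_000
    fragment_len: int = 200
    bin_size: int = 5_000
    # screen scenario
    n_marine_specific: int = 8
    n_marine_absent: int = 2
    n_stream_absent: int = 2
    n_unmarked: int = 1
    n_deletions: int = 3
    baseline_depth: float = 30.0
    # minimum TSS spacing between planted genes, so one gene's planted
    # upstream peak or coverage gap cannot reach another's search window
    screen_min_separation: int = 30_000

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_out <= 0.1 and 0.0 <= self.theta_in <= 0.1):
            raise ValueError("theta must lie in [0, 0.1]")
        if self.chrom_len < 10 * 10_000:
            raise ValueError("chrom_len must be >= 10 windows of 10 kb")
        if self.sigma_log_tpm <= 0:
            raise ValueError("sigma_log_tpm must be positive")
        planted = (self.n_marine_absent + self.n_stream_absent
                   + self.n_unmarked + self.n_deletions)
        if planted > self.n_marine_specific:
            raise ValueError(
                "planted screen classes exceed n_marine_specific")


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng((cfg.seed, stream))


def simulate_annotation(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[GeneModel], dict[str, int]]:
    """Non-overlapping genes with 1-5 exons, random strands and >= min_gap
    spacing, uniformly placed."""
    rng = rng if rng is not None else _rng(cfg, 0)
    chrom_sizes = {f"chr{i + 1}": cfg.chrom_len for i in range(cfg.n_chroms)}
    genes: list[GeneModel] = []
    per_chrom = np.full(cfg.n_chroms, cfg.n_genes // cfg.n_chroms)
    per_chrom[: cfg.n_genes % cfg.n_chroms] += 1
    gid = 0
    for ci, chrom in enumerate(chrom_sizes):
        n = int(per_chrom[ci])
        if n == 0:
            continue
        lengths = rng.integers(cfg.gene_min_len, cfg.gene_max_len + 1, size=n)
        needed = int(lengths.sum()) + (n + 1) * cfg.min_gap
        if needed > cfg.chrom_len:
            raise ValueError(
                f"{n} genes do not fit on {chrom} ({needed} bp needed, "
                f"{cfg.chrom_len} available); increase chrom_len"
            )
        slack = cfg.chrom_len - needed
        extra = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
        pos = cfg.min_gap + extra[0]
        for i in range(n):
            start, end = int(pos), int(pos + lengths[i])
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"g{gid:05d}"
            gid += 1
            genes.append(
                _make_gene(gene_id, chrom, start, end, strand, rng)
            )
            pos = end + cfg.min_gap + extra[i + 1]
    return genes, chrom_sizes


def _make_gene(
    gene_id: str, chrom: str, start: int, end: int, strand: str,
    rng: np.random.Generator,
) -> GeneModel:
    n_exons = int(rng.integers(1, 6))
    if n_exons == 1:
        exons = [(start, end)]
    else:
        interior = rng.choice(
            np.arange(start + 1, end - 1), size=2 * (n_exons - 1),
            replace=False,
        )
        bnds = np.concatenate(([start], np.sort(interior), [end]))
        exons = [(int(bnds[2 * i]), int(bnds[2 * i + 1]))
                 for i in range(n_exons)]
    exon_ivs = tuple(GenomicInterval(chrom, a, b, strand) for a, b in exons)
    span = GenomicInterval(chrom, start, end, strand)
    transcripts = [Transcript(f"{gene_id}.t1", span, exon_ivs)]
    if n_exons > 1 and rng.random() < 0.5:
        # a second isoform using a contiguous subset of exons
        lo = int(rng.integers(0, n_exons - 1))
        hi = int(rng.integers(lo + 1, n_exons))
        sub = exon_ivs[lo:hi + 1]
        transcripts.append(
            Transcript(
                f"{gene_id}.t2",
                GenomicInterval(chrom, sub[0].start, sub[-1].end, strand),
                sub,
            )
        )
    return GeneModel(gene_id, tuple(transcripts))


def _has_intergenic(index: GeneIndex, chrom_sizes: Mapping[str, int],
                    rng: np.random.Generator, tries: int = 50) -> bool:
    for _ in range(tries):
        chrom = list(chrom_sizes)[int(rng.integers(0, len(chrom_sizes)))]
        pos = int(rng.integers(0, chrom_sizes[chrom]))
        if all(index.gene_category_at(g, pos) is None
               for g in index.candidate_genes(chrom, pos)):
            return True
    return False


def simulate_peaks(
    cfg: SimulationConfig,
    genes: Sequence[GeneModel],
    chrom_sizes: Mapping[str, int],
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, list[Peak]], pd.DataFrame]:
    """Per-mark peaks whose centers follow the mark's category bias.

    Each peak's truth category is its center's classification, checked
    against :func:`classify_peak` so the truth table is consistent by
    construction.
    """
    rng = rng if rng is not None else _rng(cfg, 1)
    index = GeneIndex(genes, chrom_sizes)
    chroms = list(chrom_sizes)
    have_genes = len(genes) > 0
    has_intron = any(
        sum(e.length for e in g.exon_union()) < g.interval.length for g in genes
    )
    peaks: dict[str, list[Peak]] = {}
    truth_rows = []
    for mark, count in cfg.peak_counts.items():
        bias = dict(cfg.category_bias.get(mark, _DEFAULT_BIAS["H3K4me1"]))
        if not have_genes:
            unattainable = [c for c in bias if c != "INTERGENIC"]
        else:
            unattainable = [] if has_intron else ["INTRON"]
        for cat in unattainable:
            if bias.get(cat, 0) > 0:
                logger.warning(
                    "simulate_peaks: no %s region available; reweighting", cat)
                bias[cat] = 0.0
        cats = list(bias)
        w = np.array([bias[c] for c in cats], dtype=float)
        if w.sum() == 0:
            raise ValueError(f"no attainable category for mark {mark}")
        w = w / w.sum()
        mark_peaks: list[Peak] = []
        for i in range(count):
            target = Category(cats[int(rng.choice(len(cats), p=w))])
            peak, ann = _place_peak(cfg, target, index, genes, chroms,
                                    chrom_sizes, mark, rng)
            mark_peaks.append(peak)
            truth_rows.append(
                {
                    "mark": mark,
                    "name": peak.name,
                    "chrom": peak.chrom,
                    "start": peak.interval.start,
                    "end": peak.interval.end,
                    "category": ann.category.value,
                    "gene_id": ann.assigned_gene or ".",
                }
            )
        # stable names per mark
        mark_peaks = [
            Peak(p.interval, p.mark, p.sample_id, p.score,
                 name=f"{mark}_{j:04d}")
            for j, p in enumerate(mark_peaks)
        ]
        for j, p in enumerate(mark_peaks):
            truth_rows[len(truth_rows) - count + j]["name"] = p.name
        peaks[mark] = mark_peaks
    return peaks, pd.DataFrame(truth_rows)


def _place_peak(cfg, target, index, genes, chroms, chrom_sizes, mark, rng,
                max_tries: int = 300):
    last = None
    for _ in range(max_tries):
        if target is Category.INTERGENIC or not genes:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            center = int(rng.integers(0, chrom_sizes[chrom]))
        else:
            g = genes[int(rng.integers(0, len(genes)))]
            chrom = g.chrom
            if target is Category.PROMOTER_TSS:
                w = index._windows[g.gene_id][0]
            elif target is Category.TTS:
                w = index._windows[g.gene_id][1]
            elif target is Category.EXON:
                ex = g.exon_union()
                w = ex[int(rng.integers(0, len(ex)))]
            else:  # INTRON
                w = g.interval
            center = int(rng.integers(w.start, w.end))
        length = int(rng.integers(cfg.peak_min_len, cfg.peak_max_len + 1))
        start = int(np.clip(center - length // 2, 0,
                            chrom_sizes[chrom] - length))
        peak = Peak(GenomicInterval(chrom, start, start + length), mark,
                    "sim", name=None)
        ann = classify_peak(peak, index)
        last = (peak, ann)
        if ann.category is target:
            return peak, ann
    logger.warning("simulate_peaks: giving up on category %s for %s; "
                   "keeping %s", target.value, mark, last[1].category.value)
    return last


def simulate_expression(
    cfg: SimulationConfig,
    genes: Sequence[GeneModel],
    peaks: Mapping[str, Sequence[Peak]],
    chrom_sizes: Optional[Mapping[str, int]] = None,
    rng: Optional[np.random.Generator] = None,
    samples: Sequence[str] = ("rep1", "rep2"),
) -> tuple[ExpressionTable, dict[str, float], pd.DataFrame]:
    """Expression and dN/dS tables with planted mark effects.

    ln(TPM+1) ~ Normal(mu + delta_active * [active genic peak]
    - delta_repressive * [H3K27me3 genic peak], sigma), truncated at 0;
    dN/dS = exp(base - slope * ln(TPM+1) + noise).  Returns the expression
    table, the dN/dS mapping and a per-gene truth table of planted flags.
    """
    rng = rng if rng is not None else _rng(cfg, 2)
    index = GeneIndex(genes, chrom_sizes)
    active: set[str] = set()
    repressed: set[str] = set()
    from .annotate import GENIC_CATEGORIES

    for mark, plist in peaks.items():
        for ann in annotate_peaks(list(plist), index):
            if ann.category in GENIC_CATEGORIES and ann.assigned_gene:
                if mark in ACTIVE_MARKS:
                    active.add(ann.assigned_gene)
                elif mark == "H3K27me3":
                    repressed.add(ann.assigned_gene)
    rows = {}
    tx2gene = {}
    truth_rows = []
    dnds: dict[str, float] = {}
    for g in genes:
        shift = (cfg.delta_active * (g.gene_id in active)
                 - cfg.delta_repressive * (g.gene_id in repressed))
        log_tpm = np.maximum(
            rng.normal(cfg.mu_log_tpm + shift, cfg.sigma_log_tpm,
                       size=len(samples)),
            0.0,
        )
        tpm = np.expm1(log_tpm)
        n_tx = len(g.transcripts)
        split = rng.dirichlet(np.ones(n_tx)) if n_tx > 1 else np.ones(1)
        for t, frac in zip(g.transcripts, split):
            rows[t.transcript_id] = tpm * frac
            tx2gene[t.transcript_id] = g.gene_id
        dnds[g.gene_id] = float(
            np.exp(cfg.dnds_base - cfg.dnds_slope * log_tpm[0]
                   + rng.normal(0.0, cfg.dnds_noise))
        )
        truth_rows.append(
            {
                "gene_id": g.gene_id,
                "active_mark": g.gene_id in active,
                "repressive_mark": g.gene_id in repressed,
                "mean_log_tpm": cfg.mu_log_tpm + shift,
            }
        )
    tpm_df = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=list(samples))
    expr = ExpressionTable(tpm_df, tx2gene)
    return expr, dnds, pd.DataFrame(truth_rows)


def simulate_genotypes(
    cfg: SimulationConfig,
    peaks: Sequence[Peak],
    chrom_sizes: Mapping[str, int],
    rng: Optional[np.random.Generator] = None,
) -> GenotypeMatrix:
    """Two-population diploid genotypes: each base is polymorphic with
    probability theta_in inside any peak, theta_out elsewhere; allele
    frequencies per population are symmetric-Beta draws; genotypes are
    binomial(2, p)."""
    rng = rng if rng is not None else _rng(cfg, 3)
    n = cfg.n_samples_per_pop
    samples = [f"pop1_{i}" for i in range(n)] + [f"pop2_{i}" for i in range(n)]
    populations = {s: ("pop1" if s.startswith("pop1") else "pop2")
                   for s in samples}
    data = {}
    for chrom, length in chrom_sizes.items():
        theta = np.full(length, cfg.theta_out)
        for p in peaks:
            if p.chrom == chrom:
                theta[p.interval.start:min(p.interval.end, length)] = cfg.theta_in
        pos = np.flatnonzero(rng.random(length) < theta).astype(np.int64)
        if pos.size == 0:
            continue
        geno = np.empty((pos.size, 2 * n), dtype=np.int8)
        for k in range(2):
            freq = rng.beta(cfg.beta_shape, cfg.beta_shape, size=pos.size)
            geno[:, k * n:(k + 1) * n] = rng.binomial(
                2, freq[:, None], size=(pos.size, n)
            ).astype(np.int8)
        if cfg.missing_rate > 0:
            miss = rng.random(geno.shape) < cfg.missing_rate
            geno[miss] = GenotypeMatrix.MISSING
        data[chrom] = (pos, geno)
    return GenotypeMatrix(samples, populations, data,
                          chrom_lengths=chrom_sizes)


def simulate_fragments(
    cfg: SimulationConfig,
    chrom_sizes: Mapping[str, int],
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, list[GenomicInterval]], dict[str, int]]:
    """Per-sample fragment sets drawn from planted bin-intensity profiles.

    ``n_profiles`` Dirichlet profiles over genome bins, each sampled by
    ``reps_per_profile`` replicate samples; replicates of a profile share
    the same multinomial bin weights, so they correlate strongly while
    different profiles do not.  Returns fragments per sample and the truth
    mapping sample -> profile index.
    """
    rng = rng if rng is not None else _rng(cfg, 4)
    chroms = list(chrom_sizes)
    nbins = [int(np.ceil(chrom_sizes[c] / cfg.bin_size)) for c in chroms]
    total_bins = int(np.sum(nbins))
    offsets = np.concatenate(([0], np.cumsum(nbins)))
    out: dict[str, list[GenomicInterval]] = {}
    truth: dict[str, int] = {}
    for pi in range(cfg.n_profiles):
        weights = rng.dirichlet(np.full(total_bins, 0.5))
        for ri in range(cfg.reps_per_profile):
            sid = f"profile{pi}_rep{ri}"
            counts = rng.multinomial(cfg.fragments_per_sample, weights)
            frags: list[GenomicInterval] = []
            for ci, chrom in enumerate(chroms):
                sub = counts[offsets[ci]:offsets[ci + 1]]
                for b in np.flatnonzero(sub):
                    bin_start = int(b) * cfg.bin_size
                    bin_end = min(bin_start + cfg.bin_size, chrom_sizes[chrom])
                    starts = rng.integers(bin_start, bin_end, size=int(sub[b]))
                    for s in starts:
                        e = min(int(s) + cfg.fragment_len, chrom_sizes[chrom])
                        frags.append(GenomicInterval(chrom, int(s), e))
            frags.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
            out[sid] = frags
            truth[sid] = pi
    return out, truth


@dataclass
class ScreenScenario:
    expr: ExpressionTable
    design: EcotypeExpressionDesign
    marine_cov: CoverageTrack
    stream_cov: CoverageTrack
    peaks: list[Peak]          # active-mark peaks incl. planted upstream ones
    truth: dict[str, list[str]]


def _carve_track(
    chrom_sizes: Mapping[str, int],
    depth: float,
    gaps: Sequence[GenomicInterval],
) -> CoverageTrack:
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    for g in gaps:
        by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    runs: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, length in chrom_sizes.items():
        merged: list[list[int]] = []
        for s, e in sorted(by_chrom.get(chrom, [])):
            s, e = max(s, 0), min(e, length)
            if e <= s:
                continue
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        rs: list[tuple[int, int, float]] = []
        pos = 0
        for s, e in merged:
            if s > pos:
                rs.append((pos, s, depth))
            pos = e
        if pos < length:
            rs.append((pos, length, depth))
        runs[chrom] = rs
    return CoverageTrack(runs)


def simulate_screen_scenario(
    cfg: SimulationConfig,
    genes: Sequence[GeneModel],
    peaks: Mapping[str, Sequence[Peak]],
    chrom_sizes: Mapping[str, int],
    rng: Optional[np.random.Generator] = None,
) -> ScreenScenario:
    """Ecotype expression plus whole-genome coverage tracks with planted
    marine-specific genes, gene-body absences and stream deletions of marked
    upstream regions.

    By construction exactly the planted genes satisfy the marine-specificity
    criteria (background genes that would pass by chance are redrawn), so
    the truth table is the complete ground truth for the cascade.
    """
    rng = rng if rng is not None else _rng(cfg, 5)
    if len(genes) < cfg.n_marine_specific:
        raise ValueError("not enough genes for the requested scenario")
    background_active = [
        p for m in ("H3K4me1", "H3K4me3") for p in peaks.get(m, [])
    ]
    from .screen import upstream_region

    gene_by_id = {g.gene_id: g for g in genes}
    all_ids = [g.gene_id for g in genes]
    # greedy pick with pairwise TSS separation so planted effects stay
    # confined to their own gene; relax the spacing only if space runs out
    chosen: list[str] = []
    sep = cfg.screen_min_separation
    while True:
        for _attempt in range(20):
            order = [str(x) for x in rng.permutation(all_ids)]
            chosen = []
            for gid in order:
                g = gene_by_id[gid]
                if all(
                    gene_by_id[c].chrom != g.chrom
                    or abs(gene_by_id[c].tss - g.tss) >= sep
                    for c in chosen
                ):
                    chosen.append(gid)
                if len(chosen) == cfg.n_marine_specific:
                    break
            if len(chosen) == cfg.n_marine_specific:
                break
        if len(chosen) == cfg.n_marine_specific:
            break
        if sep == 0:
            raise ValueError(
                "cannot place the requested number of planted genes"
            )
        sep //= 2
        logger.warning(
            "simulate_screen_scenario: relaxing planted-gene spacing to %d",
            sep,
        )
    i = 0
    marine_absent = chosen[i:i + cfg.n_marine_absent]; i += cfg.n_marine_absent
    stream_absent = chosen[i:i + cfg.n_stream_absent]; i += cfg.n_stream_absent
    unmarked = chosen[i:i + cfg.n_unmarked]; i += cfg.n_unmarked
    deletions = chosen[i:i + cfg.n_deletions]; i += cfg.n_deletions
    intact_marked = chosen[i:]

    # the chosen genes' upstream state is planted below; background active
    # peaks that happen to sit in a chosen gene's search window are dropped
    # so the planted state is the only signal there
    windows = [upstream_region(gene_by_id[gid], 10_000) for gid in chosen]
    background_active = [
        p for p in background_active
        if not any(p.interval.overlaps(w) for w in windows)
    ]

    # plant one active upstream peak for every gene that must show marks
    planted_peaks: list[Peak] = []
    deletion_gaps: list[GenomicInterval] = []
    for gid in deletions + intact_marked:
        g = gene_by_id[gid]
        length = int(rng.integers(400, 1200))
        offset = int(rng.integers(1_500, 7_000))  # upstream of TSS
        if g.strand == "+":
            start = max(g.tss - offset - length, 0)
        else:
            start = min(g.tss + offset, chrom_sizes[g.chrom] - length)
        iv = GenomicInterval(g.chrom, start, start + length)
        mark = "H3K4me1" if rng.random() < 0.5 else "H3K4me3"
        planted_peaks.append(Peak(iv, mark, "sim", name=f"planted_{gid}"))
        if gid in deletions:
            deletion_gaps.append(iv)

    marine_gaps = [gene_by_id[g].interval for g in marine_absent]
    stream_gaps = [gene_by_id[g].interval for g in stream_absent] + deletion_gaps
    marine_cov = _carve_track(chrom_sizes, cfg.baseline_depth, marine_gaps)
    stream_cov = _carve_track(chrom_sizes, cfg.baseline_depth, stream_gaps)

    # ecotype expression: 4 + 4 + 4 samples
    m_fw = tuple(f"marine_fw_{i}" for i in range(1, 5))
    m_sw = tuple(f"marine_sw_{i}" for i in range(1, 5))
    s_fw = tuple(f"stream_fw_{i}" for i in range(1, 5))
    design = EcotypeExpressionDesign(
        {MARINE_FW: m_fw, MARINE_SW: m_sw, STREAM_FW: s_fw}
    )
    samples = list(m_fw) + list(m_sw) + list(s_fw)
    gene_tpm = np.expm1(
        np.maximum(
            rng.normal(cfg.mu_log_tpm, cfg.sigma_log_tpm,
                       size=(len(genes), len(samples))),
            0.0,
        )
    )
    gids = [g.gene_id for g in genes]
    df = pd.DataFrame(gene_tpm, index=gids, columns=samples)
    specific = set(chosen)
    for gid in chosen:
        df.loc[gid, list(m_fw)] = rng.uniform(80, 150, size=4)
        df.loc[gid, list(m_sw)] = rng.uniform(20, 60, size=4)
        df.loc[gid, list(s_fw)] = rng.uniform(0.0, 1.0, size=4)
    # redraw background genes that would pass the criteria by chance, so the
    # planted set is exactly the marine-specific set
    for _ in range(100):
        mfw_mean = df[list(m_fw)].mean(axis=1)
        sfw_mean = df[list(s_fw)].mean(axis=1)
        msw_min = df[list(m_sw)].min(axis=1)
        passing = (mfw_mean > 8.0 * sfw_mean) & (msw_min > 10.0)
        accidental = [g for g in df.index[passing] if g not in specific]
        if not accidental:
            break
        redraw = np.expm1(
            np.maximum(
                rng.normal(cfg.mu_log_tpm, cfg.sigma_log_tpm,
                           size=(len(accidental), len(samples))),
                0.0,
            )
        )
        df.loc[accidental, :] = redraw
    else:
        raise RuntimeError("could not neutralise accidental passers")

    # transcript-level split so the table flows through the standard reader
    tx_rows, tx2gene = {}, {}
    for g in genes:
        n_tx = len(g.transcripts)
        split = rng.dirichlet(np.ones(n_tx)) if n_tx > 1 else np.ones(1)
        for t, frac in zip(g.transcripts, split):
            tx_rows[t.transcript_id] = df.loc[g.gene_id].values * frac
            tx2gene[t.transcript_id] = g.gene_id
    expr = ExpressionTable(
        pd.DataFrame.from_dict(tx_rows, orient="index", columns=samples),
        tx2gene,
    )
    truth = {
        "marine_specific": sorted(chosen),
        "marine_absent": sorted(marine_absent),
        "stream_absent": sorted(stream_absent),
        "unmarked": sorted(unmarked),
        "deletions": sorted(deletions),
        "intact_marked": sorted(intact_marked),
    }
    return ScreenScenario(
        expr, design, marine_cov, stream_cov,
        background_active + planted_peaks, truth,
    )


@dataclass
class SyntheticDataset:
    cfg: SimulationConfig
    genes: list[GeneModel]
    chrom_sizes: dict[str, int]
    peaks: dict[str, list[Peak]]
    peak_truth: pd.DataFrame
    expr: ExpressionTable
    dnds: dict[str, float]
    expr_truth: pd.DataFrame
    genotypes: GenotypeMatrix
    fragments: dict[str, list[GenomicInterval]]
    fragment_truth: dict[str, int]
    screen: ScreenScenario

    def write(self, outdir: str | Path) -> None:
        """Write every component as plain-text files (GFF3, BED, TSV, VCF,
        bedGraph) plus JSON truth tables."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        gio.write_gff3(self.genes, out / "genes.gff3")
        gio.write_chrom_sizes(self.chrom_sizes, out / "genome.sizes")
        for mark, plist in self.peaks.items():
            gio.write_bed(plist, out / f"peaks_{mark}.bed")
        self.peak_truth.to_csv(out / "truth_peaks.tsv", sep="\t", index=False)
        gio.write_expression(self.expr, out / "tpm.tsv", out / "tx2gene.tsv")
        pd.Series(self.dnds).rename_axis("gene_id").to_csv(
            out / "dnds.tsv", sep="\t", header=False
        )
        self.expr_truth.to_csv(out / "truth_expression.tsv", sep="\t",
                               index=False)
        gio.write_vcf(self.genotypes, out / "populations.vcf")
        with open(out / "popmap.tsv", "w") as fh:
            for s in self.genotypes.samples:
                fh.write(f"{s}\t{self.genotypes.populations[s]}\n")
        for sid, frags in self.fragments.items():
            gio.write_bed(frags, out / f"fragments_{sid}.bed")
        gio.write_expression(self.screen.expr, out / "ecotype_tpm.tsv",
                             out / "ecotype_tx2gene.tsv")
        with open(out / "design.tsv", "w") as fh:
            for group in (MARINE_FW, MARINE_SW, STREAM_FW):
                for s in self.screen.design.samples(group):
                    fh.write(f"{s}\t{group}\n")
        gio.write_bedgraph(self.screen.marine_cov, out / "marine.bedgraph")
        gio.write_bedgraph(self.screen.stream_cov, out / "stream.bedgraph")
        gio.write_bed(self.screen.peaks, out / "screen_active_peaks.bed")
        truth = {
            "fragment_profiles": self.fragment_truth,
            "screen": self.screen.truth,
        }
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
        with open(out / "config.json", "w") as fh:
            json.dump(asdict(self.cfg), fh, indent=1, sort_keys=True)


def generate(cfg: SimulationConfig) -> SyntheticDataset:
    """Run every simulation stage under one seed."""
    genes, chrom_sizes = simulate_annotation(cfg)
    peaks, peak_truth = simulate_peaks(cfg, genes, chrom_sizes)
    expr, dnds, expr_truth = simulate_expression(cfg, genes, peaks, chrom_sizes)
    all_peaks = [p for plist in peaks.values() for p in plist]
    genotypes = simulate_genotypes(cfg, all_peaks, chrom_sizes)
    fragments, fragment_truth = simulate_fragments(cfg, chrom_sizes)
    screen = simulate_screen_scenario(cfg, genes, peaks, chrom_sizes)
    return SyntheticDataset(
        cfg, genes, chrom_sizes, peaks, peak_truth, expr, dnds, expr_truth,
        genotypes, fragments, fragment_truth, screen,
    )
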
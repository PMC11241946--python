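"""Five-category annotation of peaks by the genomic feature at their center.

Each peak is classified by where its center base falls: promoter/TSS
(-1 kb to +100 bp of the TSS), TTS (-100 bp to +1 kb of the TTS), exon,
intron, or intergenic (assigned to the closest gene by center-to-TSS
distance).  When the center lies in features of several genes, precedence is
PROMOTER_TSS > TTS > EXON > INTRON, with ties broken by smaller
|distance to TSS| and then gene id, so annotation is deterministic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .model import GeneModel, GenomicInterval, Peak


class Category(str, enum.Enum):
    PROMOTER_TSS = "PROMOTER_TSS"
    EXON = "EXON"
    INTRON = "INTRON"
    TTS = "TTS"
    INTERGENIC = "INTERGENIC"


#: precedence rank when a centre hits features of several genes (lower wins)
_RANK = {
    Category.PROMOTER_TSS: 0,
    Category.TTS: 1,
    Category.EXON: 2,
    Category.INTRON: 3,
}

GENIC_CATEGORIES = frozenset(
    {Category.PROMOTER_TSS, Category.EXON, Category.INTRON, Category.TTS}
)


@dataclass(frozen=True)
class PeakAnnotation:
    peak: Peak
    category: Category
    assigned_gene: Optional[str]
    distance_to_tss: Optional[int]


def peak_center(peak: Peak) -> int:
    """Center base of a peak: ``start + floor(length / 2)``."""
    iv = peak.interval
    return iv.start + (iv.end - iv.start) // 2


def promoter_window(
    gene: GeneModel,
    upstream: int = 1000,
    downstream: int = 100,
    chrom_size: Optional[int] = None,
) -> GenomicInterval:
    """Promoter/TSS window: ``upstream`` bp 5' of the TSS through
    ``downstream`` bp 3' of it, inclusive of both ends, strand-aware."""
    if gene.strand not in ("+", "-"):
        raise ValueError(
            f"gene {gene.gene_id}: promoter window undefined for strand '.'"
        )
    tss = gene.tss
    if gene.strand == "+":
        lo, hi = tss - upstream, tss + downstream + 1
    else:
        lo, hi = tss - downstream, tss + upstream + 1
    lo = max(lo, 0)
    if chrom_size is not None:
        hi = min(hi, chrom_size)
    return GenomicInterval(gene.chrom, lo, hi, gene.strand)


def tts_window(
    gene: GeneModel,
    upstream: int = 100,
    downstream: int = 1000,
    chrom_size: Optional[int] = None,
) -> GenomicInterval:
    """TTS window: ``upstream`` bp 5' of the TTS through ``downstream`` bp
    3' of it, inclusive, strand-aware."""
    if gene.strand not in ("+", "-"):
        raise ValueError(
            f"gene {gene.gene_id}: TTS window undefined for strand '.'"
        )
    tts = gene.tts
    if gene.strand == "+":
        lo, hi = tts - upstream, tts + downstream + 1
    else:
        lo, hi = tts - downstream, tts + upstream + 1
    lo = max(lo, 0)
    if chrom_size is not None:
        hi = min(hi, chrom_size)
    return GenomicInterval(gene.chrom, lo, hi, gene.strand)


def signed_tss_distance(gene: GeneModel, pos: int) -> int:
    """Distance from a position to the gene's TSS, negative when the
    position is upstream of the TSS in gene orientation."""
    if gene.strand == "-":
        return gene.tss - pos
    return pos - gene.tss


class GeneIndex:
    """Spatial index over gene footprints (span plus promoter/TTS windows)
    for center classification and nearest-TSS queries."""

    def __init__(
        self,
        genes: Sequence[GeneModel],
        chrom_sizes: Optional[Mapping[str, int]] = None,
        promoter_upstream: int = 1000,
        promoter_downstream: int = 100,
        tts_upstream: int = 100,
        tts_downstream: int = 1000,
    ) -> None:
        self.genes = {g.gene_id: g for g in genes}
        if len(self.genes) != len(genes):
            raise ValueError("duplicate gene ids")
        self.chrom_sizes = dict(chrom_sizes) if chrom_sizes else {}
        self._prom_args = (promoter_upstream, promoter_downstream)
        self._tts_args = (tts_upstream, tts_downstream)
        self._trees: dict[str, IntervalTree] = {}
        self._windows: dict[str, tuple[GenomicInterval, GenomicInterval]] = {}
        tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
        for g in genes:
            size = self.chrom_sizes.get(g.chrom)
            pw = promoter_window(g, *self._prom_args, chrom_size=size)
            tw = tts_window(g, *self._tts_args, chrom_size=size)
            self._windows[g.gene_id] = (pw, tw)
            lo = min(pw.start, tw.start, g.interval.start)
            hi = max(pw.end, tw.end, g.interval.end)
            self._trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi, g.gene_id)
            tss_by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
        self._tss: dict[str, tuple[np.ndarray, list[str]]] = {}
        for chrom, pairs in tss_by_chrom.items():
            pairs.sort()
            self._tss[chrom] = (
                np.array([p for p, _ in pairs], dtype=np.int64),
                [gid for _, gid in pairs],
            )

    def gene_category_at(self, gene_id: str, pos: int) -> Optional[Category]:
        """Category of ``pos`` with respect to one gene, or None if outside
        all of its features.  Within a gene, promoter beats TTS beats exon
        beats intron."""
        gene = self.genes[gene_id]
        pw, tw = self._windows[gene_id]
        if pw.contains(pos):
            return Category.PROMOTER_TSS
        if tw.contains(pos):
            return Category.TTS
        if gene.interval.contains(pos):
            for exon in gene.exon_union():
                if exon.contains(pos):
                    return Category.EXON
            return Category.INTRON
        return None

    def candidate_genes(self, chrom: str, pos: int) -> list[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.at(pos)]

    def nearest_gene(self, chrom: str, pos: int) -> Optional[tuple[str, int]]:
        """(gene_id, unsigned center-to-TSS distance) of the closest gene on
        the chromosome, or None if the chromosome has no genes.  Ties broken
        by gene id."""
        if chrom not in self._tss:
            return None
        tss, gids = self._tss[chrom]
        i = int(np.searchsorted(tss, pos))
        best: Optional[tuple[int, str]] = None
        for j in (i - 1, i, i + 1):
            if 0 <= j < tss.size:
                cand = (abs(int(tss[j]) - pos), gids[j])
                if best is None or cand < best:
                    best = cand
        # several genes may share the minimum distance at other indices with
        # an equal |d|; scan neighbours with the same distance for id order
        if best is not None:
            d = best[0]
            lo = int(np.searchsorted(tss, pos - d, side="left"))
            hi = int(np.searchsorted(tss, pos + d, side="right"))
            for j in range(lo, hi):
                if abs(int(tss[j]) - pos) == d and gids[j] < best[1]:
                    best = (d, gids[j])
            return best[1], best[0]
        return None


def classify_peak(peak: Peak, index: GeneIndex) -> PeakAnnotation:
    """Classify one peak by its center (see module docstring for precedence)."""
    center = peak_center(peak)
    best: Optional[tuple[int, int, str, Category]] = None
    for gid in index.candidate_genes(peak.chrom, center):
        cat = index.gene_category_at(gid, center)
        if cat is None:
            continue
        dist = signed_tss_distance(index.genes[gid], center)
        key = (_RANK[cat], abs(dist), gid, cat)
        if best is None or key[:3] < best[:3]:
            best = key
    if best is not None:
        rank, absdist, gid, cat = best
        return PeakAnnotation(
            peak, cat, gid, signed_tss_distance(index.genes[gid], center)
        )
    near = index.nearest_gene(peak.chrom, center)
    if near is None:
        return PeakAnnotation(peak, Category.INTERGENIC, None, None)
    gid, _ = near
    return PeakAnnotation(
        peak, Category.INTERGENIC, gid,
        signed_tss_distance(index.genes[gid], center),
    )


def annotate_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel] | GeneIndex,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> list[PeakAnnotation]:
    """Classify every peak, preserving input order."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes, chrom_sizes)
    return [classify_peak(p, index) for p in peaks]


@dataclass(frozen=True)
class AnnotationSummary:
    """Per-category peak counts and summed peak lengths with proportions
    (the full peak length is attributed to its center's category)."""

    counts: dict[Category, int]
    lengths: dict[Category, int]

    @property
    def count_proportions(self) -> dict[Category, float]:
        total = sum(self.counts.values())
        return {c: n / total for c, n in self.counts.items()}

    @property
    def length_proportions(self) -> dict[Category, float]:
        total = sum(self.lengths.values())
        return {c: n / total for c, n in self.lengths.items()}


def summarize_annotation(annotations: Sequence[PeakAnnotation]) -> AnnotationSummary:
    if not annotations:
        raise ValueError("cannot summarize an empty annotation set")
    counts = {c: 0 for c in Category}
    lengths = {c: 0 for c in Category}
    for a in annotations:
        counts[a.category] += 1
        lengths[a.category] += a.peak.interval.length
    counts = {c: n for c, n in counts.items() if n}
    lengths = {c: n for c, n in lengths.items() if n}
    return AnnotationSummary(counts, lengths)


def annotations_to_table(annotations: Sequence[PeakAnnotation]):
    """Flatten annotations into a DataFrame for TSV output."""
    import pandas as pd

    rows = []
    for a in annotations:
        iv = a.peak.interval
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "mark": a.peak.mark,
                "sample_id": a.peak.sample_id,
                "category": a.category.value,
                "gene_id": a.assigned_gene if a.assigned_gene else ".",
                "distance_to_tss": a.distance_to_tss
                if a.distance_to_tss is not None
                else ".",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "mark", "sample_id", "category",
                 "gene_id", "distance_to_tss"],
    )
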
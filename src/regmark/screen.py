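"""Screen for marine-specific genes and candidate cis-regulatory indels.

Three criteria pick out genes specifically expressed in the marine ecotype:
(1) mean TPM of the freshwater-acclimated marine fish exceeds ``fold`` (8x)
times the mean of the freshwater-acclimated stream fish; (2) the minimum
TPM of the seawater-acclimated marine fish is above ``min_tpm`` (10);
(3) the gene lies on an assembled chromosome.  Passing genes then run an
exclusion cascade: genes whose body is missing from the marine genome, then
from the stream genome, are excluded (expression specificity there reflects
presence/absence, not regulation); remaining genes need an active H3K4me1
and/or H3K4me3 mark upstream; finally, a stream-specific coverage gap over
that marked region calls a candidate cis-regulatory deletion.

Gene-body absence and indels are formalised as coverage-fraction rules over
whole-genome read depth (configurable min_depth / min_frac / del_frac)
standing in for visual inspection of mapped reads.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import CoverageTrack, ExpressionTable, GeneModel, GenomicInterval, Peak

logger = logging.getLogger(__name__)

MARINE_FW = "MARINE_FW"
MARINE_SW = "MARINE_SW"
STREAM_FW = "STREAM_FW"
GROUPS = (MARINE_FW, MARINE_SW, STREAM_FW)


@dataclass(frozen=True)
class EcotypeExpressionDesign:
    """Sample groups: marine fish under freshwater (1% seawater) and
    seawater (100%) acclimation, and stream fish under freshwater."""

    groups: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        missing = [g for g in GROUPS if not self.groups.get(g)]
        if missing:
            raise ValueError(f"empty/missing design groups: {missing}")
        all_samples = [s for g in GROUPS for s in self.groups[g]]
        if len(set(all_samples)) != len(all_samples):
            raise ValueError("design groups must be disjoint")

    def samples(self, group: str) -> tuple[str, ...]:
        return tuple(self.groups[group])


class Disposition(str, enum.Enum):
    EXCLUDED_MARINE_GENEBODY_ABSENT = "EXCLUDED_MARINE_GENEBODY_ABSENT"
    EXCLUDED_STREAM_GENEBODY_ABSENT = "EXCLUDED_STREAM_GENEBODY_ABSENT"
    NO_UPSTREAM_MARKS = "NO_UPSTREAM_MARKS"
    CANDIDATE_WITH_INDEL = "CANDIDATE_WITH_INDEL"
    CANDIDATE_NO_INDEL = "CANDIDATE_NO_INDEL"


class IndelType(str, enum.Enum):
    DELETION_IN_STREAM = "DELETION_IN_STREAM"
    INSERTION_IN_STREAM = "INSERTION_IN_STREAM"


@dataclass(frozen=True)
class IndelCall:
    type: IndelType
    interval: GenomicInterval


@dataclass(frozen=True)
class ScreenRecord:
    gene_id: str
    c1: bool
    c2: bool
    c3: bool
    disposition: Optional[Disposition] = None
    candidate_region: Optional[GenomicInterval] = None
    indel: Optional[IndelCall] = None

    @property
    def passed(self) -> bool:
        return self.c1 and self.c2 and self.c3


@dataclass
class ScreenConfig:
    fold: float = 8.0
    min_tpm: float = 10.0
    min_depth: float = 2.0
    min_frac: float = 0.5
    del_frac: float = 0.8
    upstream_search: int = 10_000


def flag_ecotype_specific(
    gene_tpm: pd.DataFrame,
    design: EcotypeExpressionDesign,
    fold: float = 8.0,
    min_tpm: float = 10.0,
    assembled_chroms: Optional[set[str]] = None,
    gene_chrom: Optional[Mapping[str, str]] = None,
) -> dict[str, tuple[bool, bool, bool]]:
    """Evaluate the three marine-specificity criteria per gene.

    ``gene_tpm`` is a gene x sample TPM matrix (isoforms already summed).
    c3 needs ``assembled_chroms`` and a gene -> chromosome mapping; if either
    is omitted c3 is vacuously true.
    """
    for group in GROUPS:
        missing = [s for s in design.samples(group) if s not in gene_tpm.columns]
        if missing:
            raise ValueError(f"design samples absent from table: {missing}")
    mfw = gene_tpm[list(design.samples(MARINE_FW))].mean(axis=1)
    sfw = gene_tpm[list(design.samples(STREAM_FW))].mean(axis=1)
    msw_min = gene_tpm[list(design.samples(MARINE_SW))].min(axis=1)
    out: dict[str, tuple[bool, bool, bool]] = {}
    for gid in gene_tpm.index:
        c1 = bool(mfw[gid] > fold * sfw[gid])
        c2 = bool(msw_min[gid] > min_tpm)
        if assembled_chroms is None or gene_chrom is None:
            c3 = True
        elif gid not in gene_chrom:
            logger.warning("gene %s lacks a chromosome assignment; skipped", gid)
            continue
        else:
            c3 = gene_chrom[gid] in assembled_chroms
        out[gid] = (c1, c2, c3)
    return out


def gene_body_present(
    cov: CoverageTrack,
    gene: GeneModel,
    min_depth: float = 2.0,
    min_frac: float = 0.5,
) -> bool:
    """True iff >= ``min_frac`` of gene-span bases have depth >= ``min_depth``
    in the whole-genome track — the coverage surrogate for "the gene body is
    present in this ecotype's genome"."""
    return cov.fraction_at_least(gene.interval, min_depth) >= min_frac


def upstream_region(gene: GeneModel, search: int = 10_000) -> GenomicInterval:
    """Strand-aware search window: ``search`` bp upstream of the TSS through
    100 bp downstream of it."""
    if gene.strand == "-":
        lo, hi = gene.tss - 99, gene.tss + search + 1
    else:
        lo, hi = gene.tss - search, gene.tss + 100
    return GenomicInterval(gene.chrom, max(lo, 0), hi)


def upstream_marks(
    gene: GeneModel,
    peaks: Sequence[Peak],
    search: int = 10_000,
) -> Optional[GenomicInterval]:
    """Hull of H3K4me1/H3K4me3 peak intervals intersecting the upstream
    search window, or None when no active mark is near."""
    window = upstream_region(gene, search)
    hits = [
        p.interval
        for p in peaks
        if p.mark in ("H3K4me1", "H3K4me3") and p.interval.overlaps(window)
    ]
    if not hits:
        return None
    return GenomicInterval(
        gene.chrom, min(h.start for h in hits), max(h.end for h in hits)
    )


def detect_candidate_indel(
    candidate_region: GenomicInterval,
    marine_cov: CoverageTrack,
    stream_cov: CoverageTrack,
    min_depth: float = 2.0,
    del_frac: float = 0.8,
) -> Optional[IndelCall]:
    """Call a stream-specific deletion of the candidate region.

    DELETION_IN_STREAM when >= ``del_frac`` of region bases are below
    ``min_depth`` in the stream track while >= ``del_frac`` are at or above
    it in the marine track; the maximal low-depth run is reported as the
    indel interval.
    """
    if candidate_region.length < 50:
        logger.warning("candidate region %s:%d-%d shorter than 50 bp",
                       candidate_region.chrom, candidate_region.start,
                       candidate_region.end)
    stream = stream_cov.depth_profile(candidate_region)
    marine = marine_cov.depth_profile(candidate_region)
    low_stream = stream < min_depth
    if low_stream.mean() < del_frac or (marine >= min_depth).mean() < del_frac:
        return None
    # maximal run of low stream depth
    padded = np.concatenate(([False], low_stream, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2]
    k = int(np.argmax(ends - starts))
    interval = GenomicInterval(
        candidate_region.chrom,
        candidate_region.start + int(starts[k]),
        candidate_region.start + int(ends[k]),
    )
    return IndelCall(IndelType.DELETION_IN_STREAM, interval)


@dataclass
class ScreenResult:
    records: list[ScreenRecord]
    stage_counts: dict[str, int] = field(default_factory=dict)

    def by_disposition(self, disp: Disposition) -> list[ScreenRecord]:
        return [r for r in self.records if r.disposition is disp]

    def candidates_with_indel(self) -> set[str]:
        return {
            r.gene_id
            for r in self.records
            if r.disposition is Disposition.CANDIDATE_WITH_INDEL
        }


def run_cascade(
    expr: ExpressionTable,
    design: EcotypeExpressionDesign,
    genes: Sequence[GeneModel],
    marine_cov: CoverageTrack,
    stream_cov: CoverageTrack,
    peaks: Sequence[Peak],
    config: Optional[ScreenConfig] = None,
    assembled_chroms: Optional[set[str]] = None,
) -> ScreenResult:
    """Apply the criteria then the exclusion cascade, in order: marine
    gene-body absence -> stream gene-body absence -> upstream active marks
    -> stream deletion of the marked region."""
    cfg = config or ScreenConfig()
    gene_by_id = {g.gene_id: g for g in genes}
    gene_tpm = expr.gene_tpm_matrix()
    gene_tpm = gene_tpm.loc[[g for g in gene_tpm.index if g in gene_by_id]]
    flags = flag_ecotype_specific(
        gene_tpm,
        design,
        fold=cfg.fold,
        min_tpm=cfg.min_tpm,
        assembled_chroms=assembled_chroms,
        gene_chrom={g.gene_id: g.chrom for g in genes},
    )
    records: list[ScreenRecord] = []
    counts = {
        "criteria_passed": 0,
        **{d.value: 0 for d in Disposition},
    }
    for gid in sorted(flags):
        c1, c2, c3 = flags[gid]
        if not (c1 and c2 and c3):
            records.append(ScreenRecord(gid, c1, c2, c3))
            continue
        counts["criteria_passed"] += 1
        gene = gene_by_id[gid]
        if not gene_body_present(marine_cov, gene, cfg.min_depth, cfg.min_frac):
            disp, region, indel = (
                Disposition.EXCLUDED_MARINE_GENEBODY_ABSENT, None, None
            )
        elif not gene_body_present(stream_cov, gene, cfg.min_depth, cfg.min_frac):
            disp, region, indel = (
                Disposition.EXCLUDED_STREAM_GENEBODY_ABSENT, None, None
            )
        else:
            region = upstream_marks(gene, peaks, cfg.upstream_search)
            if region is None:
                disp, indel = Disposition.NO_UPSTREAM_MARKS, None
            else:
                indel = detect_candidate_indel(
                    region, marine_cov, stream_cov, cfg.min_depth, cfg.del_frac
                )
                disp = (
                    Disposition.CANDIDATE_WITH_INDEL
                    if indel is not None
                    else Disposition.CANDIDATE_NO_INDEL
                )
        counts[disp.value] += 1
        records.append(ScreenRecord(gid, c1, c2, c3, disp, region, indel))
    logger.info("screen cascade: %s", counts)
    return ScreenResult(records, counts)


def screen_to_table(result: ScreenResult) -> pd.DataFrame:
    rows = []
    for r in result.records:
        rows.append(
            {
                "gene_id": r.gene_id,
                "c1_fold": r.c1,
                "c2_min_tpm": r.c2,
                "c3_assembled": r.c3,
                "disposition": r.disposition.value if r.disposition else ".",
                "candidate_region": (
                    f"{r.candidate_region.chrom}:{r.candidate_region.start}"
                    f"-{r.candidate_region.end}"
                    if r.candidate_region
                    else "."
                ),
                "indel_type": r.indel.type.value if r.indel else ".",
                "indel_interval": (
                    f"{r.indel.interval.chrom}:{r.indel.interval.start}"
                    f"-{r.indel.interval.end}"
                    if r.indel
                    else "."
                ),
            }
        )
    return pd.DataFrame(rows)
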
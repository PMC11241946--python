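"""Core domain types shared by every stage of the pipeline.

All coordinates are 0-based, half-open ``[start, end)`` on the forward
reference strand, regardless of the file format they came from (GFF and VCF
are converted on ingest).  A gene is represented at gene level: its span is
the union of its transcript spans and its TSS/TTS are the strand-aware 5'/3'
ends of that span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

VALID_MARKS = ("H3K4me1", "H3K4me3", "H3K27me3", "H3K9me3", "ATAC", "IgG")
ACTIVE_MARKS = ("H3K4me1", "H3K4me3", "ATAC")
REPRESSIVE_MARKS = ("H3K27me3", "H3K9me3")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        for exon in exons:
            if exon.start < self.interval.start or exon.end > self.interval.end:
                raise ValueError(
                    f"exon {exon.start}-{exon.end} outside transcript span of "
                    f"{self.transcript_id}"
                )
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )


@dataclass(frozen=True)
class GeneModel:
    """A gene as the union of its transcripts, with strand-aware TSS/TTS."""

    gene_id: str
    transcripts: tuple[Transcript, ...]
    interval: GenomicInterval = field(init=False)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        chroms = {t.interval.chrom for t in self.transcripts}
        strands = {t.interval.strand for t in self.transcripts}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(
                f"gene {self.gene_id}: transcripts disagree on chrom/strand"
            )
        start = min(t.interval.start for t in self.transcripts)
        end = max(t.interval.end for t in self.transcripts)
        object.__setattr__(
            self,
            "interval",
            GenomicInterval(chroms.pop(), start, end, strands.pop()),
        )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """Strand-aware transcription start: 5' end of the gene span."""
        if self.strand == "-":
            return self.interval.end - 1
        return self.interval.start

    @property
    def tts(self) -> int:
        """Strand-aware transcription termination: 3' end of the gene span."""
        if self.strand == "-":
            return self.interval.start
        return self.interval.end - 1

    def exon_union(self) -> tuple[GenomicInterval, ...]:
        """Merged union of exons across all isoforms."""
        exons = sorted(
            (e for t in self.transcripts for e in t.exons), key=lambda e: e.start
        )
        merged: list[list[int]] = []
        for e in exons:
            if merged and e.start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e.end)
            else:
                merged.append([e.start, e.end])
        return tuple(
            GenomicInterval(self.chrom, s, e, self.strand) for s, e in merged
        )


@dataclass(frozen=True)
class Peak:
    """One called enrichment interval for a mark in a sample."""

    interval: GenomicInterval
    mark: str
    sample_id: str
    score: Optional[float] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mark not in VALID_MARKS:
            raise ValueError(
                f"unknown mark {self.mark!r}; expected one of {VALID_MARKS}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def center(self) -> int:
        iv = self.interval
        return iv.start + (iv.end - iv.start) // 2


class GenotypeMatrix:
    """Biallelic-site diploid allele counts for samples from two populations.

    Genotypes are stored per chromosome as an ``(n_sites, n_samples)`` int8
    array of alternate-allele counts in {0, 1, 2}, with -1 for missing.
    """

    MISSING = -1

    def __init__(
        self,
        samples: Sequence[str],
        populations: Mapping[str, str],
        data: Mapping[str, tuple[np.ndarray, np.ndarray]],
        chrom_lengths: Optional[Mapping[str, int]] = None,
    ) -> None:
        self.samples = list(samples)
        missing_pop = [s for s in self.samples if s not in populations]
        if missing_pop:
            raise ValueError(
                f"samples missing from population map: {missing_pop}"
            )
        self.populations = dict(populations)
        self.data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (pos, geno) in data.items():
            pos = np.asarray(pos, dtype=np.int64)
            geno = np.asarray(geno, dtype=np.int8)
            if geno.shape != (pos.size, len(self.samples)):
                raise ValueError(
                    f"{chrom}: genotype array shape {geno.shape} does not "
                    f"match {pos.size} sites x {len(self.samples)} samples"
                )
            if pos.size > 1 and np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: positions not strictly increasing")
            self.data[chrom] = (pos, geno)
        self.chrom_lengths = dict(chrom_lengths) if chrom_lengths else None

    @property
    def chroms(self) -> list[str]:
        return list(self.data)

    @property
    def n_sites(self) -> int:
        return sum(pos.size for pos, _ in self.data.values())

    def population_names(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            p = self.populations[s]
            if p not in seen:
                seen.append(p)
        return seen

    def sample_indices(self, population: str) -> np.ndarray:
        idx = [
            i for i, s in enumerate(self.samples)
            if self.populations[s] == population
        ]
        if not idx:
            raise ValueError(f"no samples in population {population!r}")
        return np.asarray(idx)

    def allele_counts(self, chrom: str, population: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (called allele count m, alt allele count c) for a population.

        Missing genotypes reduce m at that site rather than dropping the site.
        """
        _, geno = self.data[chrom]
        sub = geno[:, self.sample_indices(population)]
        called = sub != self.MISSING
        m = 2 * called.sum(axis=1)
        c = np.where(called, sub, 0).sum(axis=1)
        return m.astype(np.int64), c.astype(np.int64)


class ExpressionTable:
    """Per-transcript TPM values (rows) by sample (columns), with a total
    transcript-to-gene mapping."""

    def __init__(self, tpm: pd.DataFrame, tx2gene: Mapping[str, str]) -> None:
        if (tpm.values < 0).any():
            bad = tpm.stack()
            bad = bad[bad < 0].index[0]
            raise ValueError(f"negative TPM at transcript/sample {bad}")
        unmapped = [t for t in tpm.index if t not in tx2gene]
        if unmapped:
            raise ValueError(
                f"transcripts without gene mapping: {unmapped[:5]}"
            )
        self.tpm = tpm.astype(float)
        self.tx2gene = pd.Series({t: tx2gene[t] for t in tpm.index}, name="gene_id")

    @property
    def samples(self) -> list[str]:
        return list(self.tpm.columns)

    @property
    def transcripts(self) -> list[str]:
        return list(self.tpm.index)

    def gene_tpm(self, sample: str) -> pd.Series:
        """Gene-level TPM: the sum of the TPM of all isoforms of each gene."""
        if sample not in self.tpm.columns:
            raise KeyError(f"unknown sample {sample!r}")
        return self.tpm[sample].groupby(self.tx2gene).sum()

    def gene_tpm_matrix(self) -> pd.DataFrame:
        return self.tpm.groupby(self.tx2gene).sum()


class CoverageTrack:
    """Read-depth runs per chromosome: sorted, non-overlapping
    ``(start, end, depth)`` with depth >= 0.  Positions not covered by any
    run have depth 0."""

    def __init__(self, runs: Mapping[str, Sequence[tuple[int, int, float]]]) -> None:
        self.runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, rs in runs.items():
            rs = sorted(rs)
            starts = np.array([r[0] for r in rs], dtype=np.int64)
            ends = np.array([r[1] for r in rs], dtype=np.int64)
            depths = np.array([r[2] for r in rs], dtype=float)
            if np.any(depths < 0):
                raise ValueError(f"{chrom}: negative depth")
            if np.any(starts >= ends):
                raise ValueError(f"{chrom}: empty or inverted run")
            if starts.size > 1 and np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: overlapping coverage runs")
            self.runs[chrom] = (starts, ends, depths)

    @property
    def chroms(self) -> list[str]:
        return list(self.runs)

    def depth_profile(self, interval: GenomicInterval) -> np.ndarray:
        """Per-base depth over ``interval`` (length == interval length)."""
        if interval.chrom not in self.runs:
            raise KeyError(f"no coverage data for chromosome {interval.chrom!r}")
        starts, ends, depths = self.runs[interval.chrom]
        out = np.zeros(interval.length, dtype=float)
        lo = int(np.searchsorted(ends, interval.start, side="right"))
        for i in range(lo, starts.size):
            if starts[i] >= interval.end:
                break
            a = max(int(starts[i]), interval.start) - interval.start
            b = min(int(ends[i]), interval.end) - interval.start
            if b > a:
                out[a:b] = depths[i]
        return out

    def fraction_at_least(self, interval: GenomicInterval, min_depth: float) -> float:
        prof = self.depth_profile(interval)
        return float((prof >= min_depth).mean())


def iter_intervals(objs: Iterable) -> Iterable[GenomicInterval]:
    for o in objs:
        yield o if isinstance(o, GenomicInterval) else o.interval
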
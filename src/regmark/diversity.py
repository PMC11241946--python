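"""Windowed nucleotide diversity within (pi) and between (D_XY) populations.

Per-site statistics use allele counts: with m called alleles of which c are
the alternate, pi = 2 c (m - c) / (m (m - 1)) — the probability that two
alleles drawn without replacement differ — and, for two populations with
alt frequencies p1 and p2, D_XY = p1 (1 - p2) + p2 (1 - p1).  Sites are
summed over non-overlapping windows (10 kb by default) and divided by the
number of accessible sites in the window (the window length unless a mask
is supplied).  Windows with fewer than 10 SNPs are excluded.  Missing
genotypes reduce the called-allele count m rather than dropping the site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import GenomicInterval, GenotypeMatrix, Peak

logger = logging.getLogger(__name__)


def site_pi(m: int, c: int) -> float:
    """Within-population per-site diversity from allele counts.

    ``m`` called alleles, ``c`` of them alternate.  Requires m >= 2 (a site
    with fewer called alleles carries no pair to compare).
    """
    if not 0 <= c <= m:
        raise ValueError(f"alt count {c} outside [0, {m}]")
    if m < 2:
        raise ValueError("site_pi needs at least 2 called alleles")
    return 2.0 * c * (m - c) / (m * (m - 1))


def site_dxy(m1: int, c1: int, m2: int, c2: int) -> float:
    """Between-population per-site diversity from per-population counts."""
    if m1 < 1 or m2 < 1:
        raise ValueError("site_dxy needs >= 1 called allele per population")
    p1, p2 = c1 / m1, c2 / m2
    return p1 * (1.0 - p2) + p2 * (1.0 - p1)


@dataclass(frozen=True)
class DiversityWindow:
    interval: GenomicInterval
    n_snps: int
    pi: dict[str, float]          # population -> per-site pi
    dxy: float
    accessible: int               # denominator L used
    partial: bool = False         # trailing window shorter than the step

    def pi_of(self, population: str) -> float:
        return self.pi[population]


def _vector_pi(m: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Vectorised site_pi; sites with m < 2 contribute 0 (they are skipped)."""
    out = np.zeros(m.shape, dtype=float)
    ok = m >= 2
    mm, cc = m[ok].astype(float), c[ok].astype(float)
    out[ok] = 2.0 * cc * (mm - cc) / (mm * (mm - 1.0))
    return out


def windowed_diversity(
    gm: GenotypeMatrix,
    chrom_lengths: Optional[Mapping[str, int]] = None,
    window: int = 10_000,
    min_snps: int = 10,
    accessible: Optional[Mapping[str, np.ndarray]] = None,
) -> list[DiversityWindow]:
    """Tile each chromosome with non-overlapping windows and compute
    per-population pi and D_XY per window.

    ``accessible`` optionally maps chrom -> boolean per-base mask of
    callable sites; the window denominator L is then the number of callable
    bases instead of the window length.  The trailing partial window of a
    chromosome is kept, flagged, with L set to its true length.
    """
    chrom_lengths = chrom_lengths or gm.chrom_lengths
    if chrom_lengths is None:
        raise ValueError("chromosome lengths are required for windowing")
    pops = gm.population_names()
    if len(pops) != 2:
        raise ValueError(f"expected two populations, got {pops}")
    out: list[DiversityWindow] = []
    n_skipped_sites = 0
    for chrom, length in chrom_lengths.items():
        if chrom in gm.data:
            pos, _ = gm.data[chrom]
            m1, c1 = gm.allele_counts(chrom, pops[0])
            m2, c2 = gm.allele_counts(chrom, pops[1])
        else:
            pos = np.empty(0, dtype=np.int64)
            m1 = c1 = m2 = c2 = np.empty(0, dtype=np.int64)
        pi1 = _vector_pi(m1, c1)
        pi2 = _vector_pi(m2, c2)
        ok_dxy = (m1 >= 1) & (m2 >= 1)
        n_skipped_sites += int((~ok_dxy).sum())
        p1 = np.divide(c1, m1, out=np.zeros(len(c1)), where=m1 > 0)
        p2 = np.divide(c2, m2, out=np.zeros(len(c2)), where=m2 > 0)
        dxy_site = np.where(ok_dxy, p1 * (1 - p2) + p2 * (1 - p1), 0.0)

        n_windows = int(np.ceil(length / window))
        widx = pos // window
        counts = np.bincount(widx, minlength=n_windows).astype(int)
        sum_pi1 = np.bincount(widx, weights=pi1, minlength=n_windows)
        sum_pi2 = np.bincount(widx, weights=pi2, minlength=n_windows)
        sum_dxy = np.bincount(widx, weights=dxy_site, minlength=n_windows)
        for w in range(n_windows):
            if counts[w] < min_snps:
                continue
            start = w * window
            end = min(start + window, length)
            if accessible is not None and chrom in accessible:
                L = int(accessible[chrom][start:end].sum())
                if L == 0:
                    continue
            else:
                L = end - start
            out.append(
                DiversityWindow(
                    GenomicInterval(chrom, start, end),
                    int(counts[w]),
                    {pops[0]: sum_pi1[w] / L, pops[1]: sum_pi2[w] / L},
                    float(sum_dxy[w] / L),
                    accessible=L,
                    partial=(end - start) < window,
                )
            )
    if n_skipped_sites:
        logger.info("windowed_diversity: %d sites skipped (a population with "
                    "zero called alleles)", n_skipped_sites)
    return out


@dataclass(frozen=True)
class PeakOverlapComparison:
    """Rank-sum comparison of windows overlapping peaks (+) vs not (-)."""

    n_in: int
    n_out: int
    pi_population: str
    pi_median_in: float
    pi_median_out: float
    pi_statistic: float
    pi_p: float
    dxy_median_in: float
    dxy_median_out: float
    dxy_statistic: float
    dxy_p: float


def flag_peak_overlap(
    windows: Sequence[DiversityWindow], peaks: Sequence[Peak]
) -> np.ndarray:
    """Boolean per window: overlaps >= 1 bp of >= 1 peak."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append((p.interval.start, p.interval.end))
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        ms, me = [], []
        for s, e in ivs:
            if ms and s <= me[-1]:
                me[-1] = max(me[-1], e)
            else:
                ms.append(s)
                me.append(e)
        merged[chrom] = (np.array(ms), np.array(me))
    flags = np.zeros(len(windows), dtype=bool)
    for i, w in enumerate(windows):
        if w.interval.chrom not in merged:
            continue
        ms, me = merged[w.interval.chrom]
        j = int(np.searchsorted(me, w.interval.start, side="right"))
        flags[i] = j < ms.size and ms[j] < w.interval.end
    return flags


def compare_peak_overlap(
    windows: Sequence[DiversityWindow],
    peaks: Sequence[Peak],
    pi_population: Optional[str] = None,
) -> PeakOverlapComparison:
    """Compare pi and D_XY between windows inside (+) and outside (-) peaks.

    ``pi_population`` selects which population's pi is compared (defaults to
    the first); D_XY is population-symmetric.
    """
    if not windows:
        raise ValueError("no diversity windows to compare")
    pops = list(windows[0].pi)
    pi_population = pi_population or pops[0]
    flags = flag_peak_overlap(windows, peaks)
    inside = [w for w, f in zip(windows, flags) if f]
    outside = [w for w, f in zip(windows, flags) if not f]
    if not inside or not outside:
        raise ValueError(
            f"one overlap group is empty (in={len(inside)}, out={len(outside)})"
        )
    pi_in = np.array([w.pi[pi_population] for w in inside])
    pi_out = np.array([w.pi[pi_population] for w in outside])
    dxy_in = np.array([w.dxy for w in inside])
    dxy_out = np.array([w.dxy for w in outside])
    pi_res = stats.mannwhitneyu(pi_in, pi_out, alternative="two-sided")
    dxy_res = stats.mannwhitneyu(dxy_in, dxy_out, alternative="two-sided")
    return PeakOverlapComparison(
        n_in=len(inside),
        n_out=len(outside),
        pi_population=pi_population,
        pi_median_in=float(np.median(pi_in)),
        pi_median_out=float(np.median(pi_out)),
        pi_statistic=float(pi_res.statistic),
        pi_p=float(pi_res.pvalue),
        dxy_median_in=float(np.median(dxy_in)),
        dxy_median_out=float(np.median(dxy_out)),
        dxy_statistic=float(dxy_res.statistic),
        dxy_p=float(dxy_res.pvalue),
    )


def windows_to_table(
    windows: Sequence[DiversityWindow],
    peaks: Optional[Sequence[Peak]] = None,
) -> pd.DataFrame:
    flags = (
        flag_peak_overlap(windows, peaks)
        if peaks is not None
        else np.zeros(len(windows), dtype=bool)
    )
    pops = list(windows[0].pi) if windows else []
    rows = []
    for w, f in zip(windows, flags):
        row = {
            "chrom": w.interval.chrom,
            "start": w.interval.start,
            "end": w.interval.end,
            "n_snps": w.n_snps,
        }
        for p in pops:
            row[f"pi_{p}"] = w.pi[p]
        row["dxy"] = w.dxy
        row["accessible"] = w.accessible
        row["partial"] = w.partial
        if peaks is not None:
            row["in_peak"] = bool(f)
        rows.append(row)
    return pd.DataFrame(rows)
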
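"""Genome-binned fragment coverage, Spearman correlation and sample clustering.

Fragments (BED intervals) are counted into fixed-size genomic bins (5,000 bp
by default); a fragment increments every bin it overlaps.  Samples are then
compared by Spearman correlation of their genome-wide bin vectors and
clustered by average-linkage agglomeration on distance 1 - rho.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy

from .model import GenomicInterval

logger = logging.getLogger(__name__)


@dataclass
class BinnedCoverage:
    sample_id: str
    bin_size: int
    counts: dict[str, np.ndarray]  # chrom -> per-bin fragment counts

    def concatenated(self, chrom_order: Sequence[str]) -> np.ndarray:
        return np.concatenate([self.counts[c] for c in chrom_order])

    @property
    def total(self) -> int:
        return int(sum(v.sum() for v in self.counts.values()))


def bin_fragments(
    fragments: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    bin_size: int = 5_000,
    sample_id: str = "sample",
) -> BinnedCoverage:
    """Count fragments into bins tiling each chromosome.

    A fragment increments every bin it overlaps by 1.  Fragments extending
    past the chromosome end are clipped with a warning.
    """
    nbins = {c: int(np.ceil(l / bin_size)) for c, l in chrom_sizes.items()}
    # difference-array accumulation: +1 at first bin, -1 past last bin
    diffs = {c: np.zeros(n + 1, dtype=np.int64) for c, n in nbins.items()}
    n_clipped = 0
    for frag in fragments:
        if frag.chrom not in nbins:
            raise KeyError(f"fragment on unknown chromosome {frag.chrom!r}")
        end = frag.end
        if end > chrom_sizes[frag.chrom]:
            n_clipped += 1
            end = chrom_sizes[frag.chrom]
            if frag.start >= end:
                continue
        b0 = frag.start // bin_size
        b1 = (end - 1) // bin_size
        diffs[frag.chrom][b0] += 1
        diffs[frag.chrom][b1 + 1] -= 1
    if n_clipped:
        logger.warning("bin_fragments: clipped %d fragments beyond chromosome "
                       "ends", n_clipped)
    counts = {c: np.cumsum(d[:-1]) for c, d in diffs.items()}
    return BinnedCoverage(sample_id, bin_size, counts)


@dataclass
class CorrelationMatrix:
    sample_ids: list[str]
    rho: np.ndarray  # symmetric, diagonal 1

    def pair(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.rho[i, j])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rho, index=self.sample_ids,
                            columns=self.sample_ids)


def correlation_matrix(
    coverages: Sequence[BinnedCoverage], drop_zero_bins: bool = False
) -> CorrelationMatrix:
    """Pairwise Spearman correlation of genome-wide bin vectors.

    All samples must share binning.  ``drop_zero_bins`` removes bins that
    are zero in every sample before correlating.
    """
    if len(coverages) < 2:
        raise ValueError("need >= 2 samples to correlate")
    first = coverages[0]
    chrom_order = sorted(first.counts)
    for cov in coverages[1:]:
        if cov.bin_size != first.bin_size or sorted(cov.counts) != chrom_order \
                or any(cov.counts[c].size != first.counts[c].size
                       for c in chrom_order):
            raise ValueError(
                f"sample {cov.sample_id!r} binned differently from "
                f"{first.sample_id!r}"
            )
    mat = np.vstack([c.concatenated(chrom_order) for c in coverages])
    if drop_zero_bins:
        mat = mat[:, mat.any(axis=0)]
    for cov, row in zip(coverages, mat):
        if row.size == 0 or np.all(row == row[0]):
            raise ValueError(
                f"sample {cov.sample_id!r} has a constant bin vector; "
                "Spearman rho is undefined"
            )
    rho = stats.spearmanr(mat.T).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-sample case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix([c.sample_id for c in coverages], rho)


@dataclass
class Dendrogram:
    sample_ids: list[str]   # leaf order = id-sorted input
    linkage: np.ndarray     # scipy linkage matrix

    def merge_heights(self) -> list[float]:
        return [float(h) for h in self.linkage[:, 2]]

    def siblings(self, a: str, b: str) -> bool:
        """True iff two samples merge with each other before anything else."""
        ia, ib = self.sample_ids.index(a), self.sample_ids.index(b)
        for row in self.linkage:
            if {int(row[0]), int(row[1])} == {ia, ib}:
                return True
        return False

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.sample_ids[node.id]
            l, r = node.left, node.right
            bl = node.dist - l.dist
            br = node.dist - r.dist
            return f"({walk(l)}:{bl:.6g},{walk(r)}:{br:.6g})"

        return walk(tree) + ";"


def cluster_samples(cm: CorrelationMatrix) -> Dendrogram:
    """Average-linkage agglomerative clustering on distance 1 - rho.

    Samples are reordered by id first so the result is invariant to input
    order (deterministic tie-breaking).
    """
    if len(cm.sample_ids) < 2:
        raise ValueError("need >= 2 samples to cluster")
    order = np.argsort(cm.sample_ids)
    ids = [cm.sample_ids[i] for i in order]
    rho = cm.rho[np.ix_(order, order)]
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    condensed = dist[np.triu_indices(len(ids), k=1)]
    Z = hierarchy.linkage(condensed, method="average")
    return Dendrogram(ids, Z)
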
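"""Gene-level integration of peaks with expression and protein evolution.

For one mark and sample, every gene falls into one of three classes: GENE
(at least one peak at the gene body — promoter, exon, intron or TTS),
INTERGENIC (only nearest-gene intergenic peaks), or NO_PEAKS.  Expression
(ln(TPM+1)) and dN/dS (ln(dN/dS+1)) are compared among classes with the
two-sided Wilcoxon rank-sum test, and TPM is correlated with dN/dS by
Spearman's rank correlation.  Genes with dN/dS >= 99 are excluded up front
because dN/dS blows up when dS approaches zero.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import GENIC_CATEGORIES, Category, PeakAnnotation
from .model import ExpressionTable, GeneModel

logger = logging.getLogger(__name__)

DNDS_EXCLUSION_THRESHOLD = 99.0


class GeneCategory(str, enum.Enum):
    GENE = "GENE"
    INTERGENIC = "INTERGENIC"
    NO_PEAKS = "NO_PEAKS"


@dataclass(frozen=True)
class GeneAssociationRecord:
    gene_id: str
    category: GeneCategory
    tpm: float
    dnds: Optional[float] = None

    @property
    def log_tpm(self) -> float:
        return math.log1p(self.tpm)

    @property
    def log_dnds(self) -> Optional[float]:
        return None if self.dnds is None else math.log1p(self.dnds)


@dataclass
class CategoryComparison:
    """Per-category group sizes and medians plus pairwise rank-sum results."""

    variable: str
    n: dict[GeneCategory, int]
    median: dict[GeneCategory, float]
    pairwise: dict[tuple[GeneCategory, GeneCategory], tuple[float, float]]
    holm_adjusted: Optional[dict[tuple[GeneCategory, GeneCategory], float]] = None

    def p_value(self, a: GeneCategory, b: GeneCategory) -> float:
        key = (a, b) if (a, b) in self.pairwise else (b, a)
        return self.pairwise[key][1]


def aggregate_isoform_tpm(expr: ExpressionTable, sample: str) -> pd.Series:
    """Gene-level TPM for one sample: the sum over the gene's isoforms."""
    return expr.gene_tpm(sample)


def classify_genes(
    annotations: Sequence[PeakAnnotation],
    genes: Sequence[GeneModel],
    restrict_to_annotated_chroms: bool = True,
) -> dict[str, GeneCategory]:
    """Three-way gene classification from one (mark, sample) annotation set.

    GENE dominates INTERGENIC: a gene with both genic and nearby intergenic
    peaks counts as GENE.  With ``restrict_to_annotated_chroms`` (default),
    genes on chromosomes where the annotation has no peaks at all are left
    out rather than called NO_PEAKS, so missing data is not read as absence
    of marks.
    """
    genic: set[str] = set()
    intergenic_near: set[str] = set()
    peak_chroms: set[str] = set()
    for a in annotations:
        peak_chroms.add(a.peak.chrom)
        if a.assigned_gene is None:
            continue
        if a.category in GENIC_CATEGORIES:
            genic.add(a.assigned_gene)
        elif a.category is Category.INTERGENIC:
            intergenic_near.add(a.assigned_gene)
    out: dict[str, GeneCategory] = {}
    for g in genes:
        if restrict_to_annotated_chroms and g.chrom not in peak_chroms:
            continue
        if g.gene_id in genic:
            out[g.gene_id] = GeneCategory.GENE
        elif g.gene_id in intergenic_near:
            out[g.gene_id] = GeneCategory.INTERGENIC
        else:
            out[g.gene_id] = GeneCategory.NO_PEAKS
    return out


def build_records(
    categories: Mapping[str, GeneCategory],
    gene_tpm: Mapping[str, float],
    dnds: Optional[Mapping[str, float]] = None,
) -> list[GeneAssociationRecord]:
    """Join classification, expression and (optionally filtered) dN/dS.

    Genes missing from the expression table are skipped with a warning.
    """
    records = []
    n_skipped = 0
    for gid, cat in categories.items():
        if gid not in gene_tpm:
            n_skipped += 1
            continue
        records.append(
            GeneAssociationRecord(
                gid, cat, float(gene_tpm[gid]),
                dnds=float(dnds[gid]) if dnds and gid in dnds else None,
            )
        )
    if n_skipped:
        logger.warning("build_records: %d genes missing from expression table",
                       n_skipped)
    return records


def filter_dnds(raw: Mapping[str, float]) -> dict[str, float]:
    """Drop genes with dN/dS >= 99 (inclusive); dS near zero makes the ratio
    unreliable.  Negative values are invalid."""
    out = {}
    removed = 0
    for gid, value in raw.items():
        if value < 0:
            raise ValueError(f"negative dN/dS for gene {gid}: {value}")
        if value >= DNDS_EXCLUSION_THRESHOLD:
            removed += 1
        else:
            out[gid] = float(value)
    if removed:
        logger.info("filter_dnds: removed %d genes with dN/dS >= %g",
                    removed, DNDS_EXCLUSION_THRESHOLD)
    return out


def _rank_sum(x: np.ndarray, y: np.ndarray, exact_max_n: int = 50) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U).  Exact null for small
    groups, normal approximation with tie correction otherwise.  Two
    identical all-tied groups give P = 1 by convention."""
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return float(len(x) * len(y) / 2), 1.0
    method = "exact" if max(len(x), len(y)) <= exact_max_n else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _compare(
    records: Sequence[GeneAssociationRecord],
    values_of,
    variable: str,
    holm: bool = False,
) -> CategoryComparison:
    groups: dict[GeneCategory, list[float]] = {}
    for r in records:
        v = values_of(r)
        if v is None:
            continue
        groups.setdefault(r.category, []).append(v)
    nonempty = [c for c in GeneCategory if groups.get(c)]
    if len(nonempty) < 2:
        raise ValueError(
            f"need >= 2 non-empty categories to compare (got {len(nonempty)})"
        )
    n = {c: len(groups[c]) for c in nonempty}
    median = {c: float(np.median(groups[c])) for c in nonempty}
    pairwise: dict[tuple[GeneCategory, GeneCategory], tuple[float, float]] = {}
    for a, b in combinations(list(GeneCategory), 2):
        if a not in nonempty or b not in nonempty:
            logger.warning("comparison %s vs %s skipped: empty group", a, b)
            continue
        pairwise[(a, b)] = _rank_sum(
            np.asarray(groups[a], dtype=float), np.asarray(groups[b], dtype=float)
        )
    comp = CategoryComparison(variable, n, median, pairwise)
    if holm and pairwise:
        from statsmodels.stats.multitest import multipletests

        keys = list(pairwise)
        _, adj, _, _ = multipletests([pairwise[k][1] for k in keys],
                                     method="holm")
        comp.holm_adjusted = dict(zip(keys, adj))
    return comp


def compare_expression(
    records: Sequence[GeneAssociationRecord], holm: bool = False
) -> CategoryComparison:
    """Pairwise rank-sum comparison of ln(TPM+1) among the three classes."""
    return _compare(records, lambda r: r.log_tpm, "log_tpm", holm=holm)


def compare_dnds(
    records: Sequence[GeneAssociationRecord], holm: bool = False
) -> CategoryComparison:
    """Pairwise rank-sum comparison of ln(dN/dS+1); genes lacking dN/dS are
    dropped."""
    return _compare(records, lambda r: r.log_dnds, "log_dnds", holm=holm)


def correlate_expression_dnds(
    records: Sequence[GeneAssociationRecord],
) -> tuple[float, float]:
    """Spearman rank correlation of TPM vs dN/dS (two-sided P)."""
    pairs = [(r.tpm, r.dnds) for r in records if r.dnds is not None]
    if len(pairs) < 3:
        raise ValueError("need >= 3 genes with both TPM and dN/dS")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def records_to_table(records: Sequence[GeneAssociationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "category": r.category.value,
                "tpm": r.tpm,
                "log_tpm": r.log_tpm,
                "dnds": r.dnds if r.dnds is not None else np.nan,
                "log_dnds": r.log_dnds if r.dnds is not None else np.nan,
            }
            for r in records
        ]
    )


def comparison_to_table(comp: CategoryComparison) -> pd.DataFrame:
    rows = []
    for (a, b), (u, p) in comp.pairwise.items():
        rows.append(
            {
                "variable": comp.variable,
                "group_a": a.value,
                "group_b": b.value,
                "n_a": comp.n[a],
                "n_b": comp.n[b],
                "median_a": comp.median[a],
                "median_b": comp.median[b],
                "statistic": u,
                "p_value": p,
                "p_holm": comp.holm_adjusted[(a, b)]
                if comp.holm_adjusted
                else np.nan,
            }
        )
    return pd.DataFrame(rows)
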
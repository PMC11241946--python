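"""End-to-end orchestration: annotate -> associate -> diversity -> cluster ->
screen from one YAML config, with a JSON run report recording every filter
count.  Stages hand files to each other on disk (TSV/BED/VCF), so each one
is independently inspectable and re-runnable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import association as assoc
from . import clustering as clust
from . import diversity as div
from . import io as gio
from .annotate import GeneIndex, annotate_peaks, annotations_to_table, \
    summarize_annotation
from .screen import EcotypeExpressionDesign, ScreenConfig, run_cascade, \
    screen_to_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths and every tunable threshold of the pipeline."""

    genes: str
    chrom_sizes: str
    peaks: dict[str, str]            # mark -> BED path
    expression: Optional[str] = None
    tx2gene: Optional[str] = None
    expression_sample: Optional[str] = None
    dnds: Optional[str] = None
    vcf: Optional[str] = None
    popmap: Optional[str] = None
    fragments: dict[str, str] = field(default_factory=dict)  # sample -> BED
    ecotype_expression: Optional[str] = None
    ecotype_tx2gene: Optional[str] = None
    design: Optional[str] = None
    marine_coverage: Optional[str] = None
    stream_coverage: Optional[str] = None
    screen_peaks: Optional[str] = None
    out_dir: str = "regmark_out"
    # thresholds (defaults are the analysis constants)
    promoter_upstream: int = 1000
    promoter_downstream: int = 100
    tts_upstream: int = 100
    tts_downstream: int = 1000
    window: int = 10_000
    min_snps: int = 10
    bin_size: int = 5_000
    fold: float = 8.0
    min_tpm: float = 10.0
    min_depth: float = 2.0
    min_frac: float = 0.5
    del_frac: float = 0.8
    upstream_search: int = 10_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate_paths(self) -> None:
        paths = [self.genes, self.chrom_sizes, *self.peaks.values(),
                 self.expression, self.tx2gene, self.dnds, self.vcf,
                 self.popmap, *self.fragments.values(),
                 self.ecotype_expression, self.ecotype_tx2gene, self.design,
                 self.marine_coverage, self.stream_coverage, self.screen_peaks]
        missing = [p for p in paths if p is not None and not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")


def _read_design(path: str) -> EcotypeExpressionDesign:
    groups: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            sample, group = line.split()[:2]
            groups.setdefault(group, []).append(sample)
    return EcotypeExpressionDesign({g: tuple(s) for g, s in groups.items()})


def run_full(cfg: PipelineConfig) -> dict:
    """Run every configured stage; returns (and writes) the run report."""
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    genes = gio.parse_gene_models(cfg.genes)
    chrom_sizes = gio.parse_chrom_sizes(cfg.chrom_sizes)
    index = GeneIndex(
        genes, chrom_sizes,
        promoter_upstream=cfg.promoter_upstream,
        promoter_downstream=cfg.promoter_downstream,
        tts_upstream=cfg.tts_upstream,
        tts_downstream=cfg.tts_downstream,
    )
    report["stages"]["inputs"] = {
        "n_genes": len(genes), "n_chroms": len(chrom_sizes),
    }

    # --- annotation ---------------------------------------------------
    annotations = {}
    ann_report = {}
    for mark, path in cfg.peaks.items():
        peaks = gio.parse_peaks(path, mark, "pipeline")
        anns = annotate_peaks(peaks, index)
        annotations[mark] = (peaks, anns)
        annotations_to_table(anns).to_csv(
            out / f"annotation_{mark}.tsv", sep="\t", index=False
        )
        summary = summarize_annotation(anns) if anns else None
        ann_report[mark] = {
            "n_peaks": len(peaks),
            "category_counts": {c.value: n for c, n in summary.counts.items()}
            if summary else {},
        }
    report["stages"]["annotation"] = ann_report

    # --- association --------------------------------------------------
    if cfg.expression and cfg.tx2gene:
        expr = gio.parse_expression(cfg.expression, cfg.tx2gene)
        sample = cfg.expression_sample or expr.samples[0]
        gene_tpm = assoc.aggregate_isoform_tpm(expr, sample)
        dnds_raw = gio.parse_dnds(cfg.dnds) if cfg.dnds else None
        dnds = assoc.filter_dnds(dnds_raw) if dnds_raw else None
        assoc_report = {}
        for mark, (_peaks, anns) in annotations.items():
            cats = assoc.classify_genes(anns, genes)
            records = assoc.build_records(cats, gene_tpm, dnds)
            assoc.records_to_table(records).to_csv(
                out / f"association_{mark}.tsv", sep="\t", index=False
            )
            mark_report = {
                "n_genes": len(records),
                "category_sizes": {
                    c.value: sum(1 for r in records if r.category is c)
                    for c in assoc.GeneCategory
                },
            }
            try:
                comp = assoc.compare_expression(records)
                assoc.comparison_to_table(comp).to_csv(
                    out / f"expression_comparison_{mark}.tsv", sep="\t",
                    index=False,
                )
                mark_report["expression_p"] = {
                    f"{a.value}_vs_{b.value}": p
                    for (a, b), (_u, p) in comp.pairwise.items()
                }
            except ValueError as e:
                mark_report["expression_p"] = str(e)
            if dnds:
                try:
                    dcomp = assoc.compare_dnds(records)
                    assoc.comparison_to_table(dcomp).to_csv(
                        out / f"dnds_comparison_{mark}.tsv", sep="\t",
                        index=False,
                    )
                    rho, p = assoc.correlate_expression_dnds(records)
                    mark_report["tpm_dnds_spearman"] = {"rho": rho, "p": p}
                except ValueError as e:
                    mark_report["tpm_dnds_spearman"] = str(e)
            assoc_report[mark] = mark_report
        if dnds_raw:
            assoc_report["dnds_filtered_out"] = len(dnds_raw) - len(dnds)
        report["stages"]["association"] = assoc_report

    # --- diversity ----------------------------------------------------
    if cfg.vcf and cfg.popmap:
        popmap = gio.parse_popmap(cfg.popmap)
        gm = gio.parse_genotypes(cfg.vcf, popmap, chrom_lengths=chrom_sizes)
        windows = div.windowed_diversity(
            gm, chrom_sizes, window=cfg.window, min_snps=cfg.min_snps
        )
        div_report = {
            "n_sites": gm.n_sites,
            "n_windows_kept": len(windows),
            "skipped_vcf_records": getattr(gm, "n_skipped", 0),
        }
        all_peaks = [p for m in annotations for p in annotations[m][0]]
        div.windows_to_table(windows, all_peaks).to_csv(
            out / "diversity_windows.tsv", sep="\t", index=False
        )
        for mark, (peaks, _anns) in annotations.items():
            try:
                comp = div.compare_peak_overlap(windows, peaks)
                div_report[mark] = {
                    "n_in": comp.n_in, "n_out": comp.n_out,
                    "pi_p": comp.pi_p, "dxy_p": comp.dxy_p,
                }
            except ValueError as e:
                div_report[mark] = str(e)
        report["stages"]["diversity"] = div_report

    # --- clustering ---------------------------------------------------
    if cfg.fragments:
        covs = []
        for sid, path in sorted(cfg.fragments.items()):
            frags = [p.interval for p in gio.parse_peaks(path, "IgG", sid)]
            covs.append(
                clust.bin_fragments(frags, chrom_sizes, cfg.bin_size, sid)
            )
        cm = clust.correlation_matrix(covs)
        cm.to_frame().to_csv(out / "correlation.tsv", sep="\t")
        dend = clust.cluster_samples(cm)
        (out / "dendrogram.nwk").write_text(dend.to_newick() + "\n")
        report["stages"]["clustering"] = {
            "n_samples": len(cm.sample_ids),
            "merge_heights": dend.merge_heights(),
        }

    # --- candidate screen ---------------------------------------------
    if cfg.ecotype_expression and cfg.design:
        expr = gio.parse_expression(cfg.ecotype_expression,
                                    cfg.ecotype_tx2gene)
        design = _read_design(cfg.design)
        marine_cov = gio.parse_bedgraph(cfg.marine_coverage)
        stream_cov = gio.parse_bedgraph(cfg.stream_coverage)
        screen_peaks = []
        for mark in ("H3K4me1", "H3K4me3"):
            if mark in annotations:
                screen_peaks.extend(annotations[mark][0])
        if cfg.screen_peaks:
            # a dedicated active-mark peak file overrides the annotation set
            screen_peaks = gio.parse_peaks(cfg.screen_peaks, "H3K4me1",
                                           "screen")
        result = run_cascade(
            expr, design, genes, marine_cov, stream_cov, screen_peaks,
            ScreenConfig(
                fold=cfg.fold, min_tpm=cfg.min_tpm, min_depth=cfg.min_depth,
                min_frac=cfg.min_frac, del_frac=cfg.del_frac,
                upstream_search=cfg.upstream_search,
            ),
            assembled_chroms=set(chrom_sizes),
        )
        screen_to_table(result).to_csv(out / "screen.tsv", sep="\t",
                                       index=False)
        report["stages"]["screen"] = result.stage_counts

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
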
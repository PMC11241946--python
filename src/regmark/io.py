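"""Readers and writers for the plain-text genomic formats the pipeline touches.

Everything is normalised to 0-based half-open coordinates on ingest:
GFF/GTF features (1-based closed) and VCF positions (1-based) are shifted
here and nowhere else.  BED, broadPeak and bedGraph are already 0-based
half-open and pass through unchanged.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    CoverageTrack,
    ExpressionTable,
    GeneModel,
    GenomicInterval,
    GenotypeMatrix,
    Peak,
    Transcript,
)

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised for malformed input files, carrying file/line context."""


def _attrs_gff3(field: str) -> dict[str, str]:
    out = {}
    for item in field.rstrip(";").split(";"):
        if not item.strip():
            continue
        key, _, val = item.strip().partition("=")
        out[key] = val
    return out


def _attrs_gtf(field: str) -> dict[str, str]:
    out = {}
    for item in field.rstrip(";").split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, val = item.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def parse_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse gene models from GFF3 or GTF into gene-level :class:`GeneModel`.

    Accepts ``gene``/``mRNA``/``transcript``/``exon`` features linked by
    ``ID``/``Parent`` (GFF3) or ``gene_id``/``transcript_id`` (GTF).
    1-based closed coordinates become 0-based half-open; TSS/TTS are derived
    from the union span of each gene's transcripts, strand-aware.
    """
    path = Path(path)
    gtf = path.suffix.lower() in (".gtf", ".gff2")
    parse_attrs = _attrs_gtf if gtf else _attrs_gff3

    # feature id -> (gene hint) collected in document order
    tx_of_gene: dict[str, list[str]] = defaultdict(list)
    tx_meta: dict[str, tuple[str, int, int, str]] = {}
    tx_exons: dict[str, list[tuple[int, int]]] = defaultdict(list)
    gene_order: list[str] = []
    tx_parent_gene: dict[str, str] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attr_s = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from None
            if start1 < 1 or end1 < start1:
                raise ParseError(
                    f"{path}:{lineno}: invalid 1-based closed range "
                    f"{start1}-{end1}"
                )
            start, end = start1 - 1, end1  # to 0-based half-open
            attrs = parse_attrs(attr_s)
            ftype = ftype.lower()
            if ftype == "gene":
                gid = attrs.get("gene_id") if gtf else attrs.get("ID")
                if not gid:
                    raise ParseError(f"{path}:{lineno}: gene without an id")
                if gid not in gene_order:
                    gene_order.append(gid)
            elif ftype in ("mrna", "transcript"):
                if gtf:
                    tid, gid = attrs.get("transcript_id"), attrs.get("gene_id")
                else:
                    tid, gid = attrs.get("ID"), attrs.get("Parent")
                if not tid or not gid:
                    raise ParseError(
                        f"{path}:{lineno}: transcript without id/parent"
                    )
                tx_meta[tid] = (chrom, start, end, strand)
                tx_parent_gene[tid] = gid
                tx_of_gene[gid].append(tid)
                if gid not in gene_order:
                    gene_order.append(gid)
            elif ftype == "exon":
                tid = attrs.get("transcript_id") if gtf else attrs.get("Parent")
                if not tid:
                    raise ParseError(
                        f"{path}:{lineno}: exon without a parent transcript "
                        f"(attributes: {attr_s!r})"
                    )
                tx_exons[tid].append((start, end))
                if gtf and tid not in tx_meta:
                    gid = attrs.get("gene_id")
                    if not gid:
                        raise ParseError(
                            f"{path}:{lineno}: exon without gene_id"
                        )
                    tx_parent_gene[tid] = gid
                    tx_of_gene[gid].append(tid)
                    tx_meta[tid] = (chrom, start, end, strand)
                    if gid not in gene_order:
                        gene_order.append(gid)

    orphans = set(tx_exons) - set(tx_meta)
    if orphans:
        name = sorted(orphans)[0]
        raise ParseError(
            f"{path}: exon references unknown parent transcript {name!r}"
        )

    genes: list[GeneModel] = []
    for gid in gene_order:
        tids = tx_of_gene.get(gid)
        if not tids:
            continue  # gene line without transcripts carries no exon structure
        transcripts = []
        for tid in tids:
            chrom, start, end, strand = tx_meta[tid]
            exons = tx_exons.get(tid) or [(start, end)]
            # GTF transcripts inferred from exon lines: span = exon hull
            if tid not in tx_exons and not exons:
                exons = [(start, end)]
            lo = min(min(e[0] for e in exons), start)
            hi = max(max(e[1] for e in exons), end)
            transcripts.append(
                Transcript(
                    tid,
                    GenomicInterval(chrom, lo, hi, strand),
                    tuple(GenomicInterval(chrom, a, b, strand) for a, b in exons),
                )
            )
        genes.append(GeneModel(gid, tuple(transcripts)))
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tregmark\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={g.gene_id}\n"
            )
            for t in g.transcripts:
                ti = t.interval
                fh.write(
                    f"{ti.chrom}\tregmark\tmRNA\t{ti.start + 1}\t{ti.end}\t.\t"
                    f"{ti.strand}\t.\tID={t.transcript_id};Parent={g.gene_id}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{e.chrom}\tregmark\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{e.strand}\t.\tParent={t.transcript_id}\n"
                    )


def parse_peaks(path: str | Path, mark: str, sample_id: str) -> list[Peak]:
    """Parse a BED3/BED5/broadPeak file into :class:`Peak` records.

    BED is already 0-based half-open.  Column 4 is kept as the peak name and
    column 5 (when present) as the score.
    """
    peaks: list[Peak] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns"
                )
            chrom = cols[0]
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            if start >= end:
                raise ParseError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            name = cols[3] if len(cols) > 3 and cols[3] != "." else None
            score: Optional[float] = None
            if len(cols) > 4 and cols[4] not in (".", ""):
                score = float(cols[4])
            peaks.append(
                Peak(GenomicInterval(chrom, start, end), mark, sample_id,
                     score=score, name=name)
            )
    return peaks


def write_bed(intervals, path: str | Path) -> None:
    """Write peaks or bare intervals as BED (score column when present)."""
    with open(path, "w") as fh:
        for obj in intervals:
            if isinstance(obj, Peak):
                iv, name, score = obj.interval, obj.name, obj.score
            else:
                iv, name, score = obj, None, None
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if name is not None or score is not None:
                cols.append(name if name is not None else ".")
            if score is not None:
                cols.append(f"{score:g}")
            fh.write("\t".join(cols) + "\n")


def parse_genotypes(
    path: str | Path,
    pop_map: Mapping[str, str],
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> GenotypeMatrix:
    """Parse a VCF into a :class:`GenotypeMatrix` via cyvcf2.

    Multi-allelic and non-SNP records are skipped (counted and logged);
    1-based POS becomes 0-based; ``./.`` becomes missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in pop_map]
    if missing:
        raise ValueError(
            f"VCF sample(s) absent from population map: {missing}"
        )
    pos_by_chrom: dict[str, list[int]] = defaultdict(list)
    geno_by_chrom: dict[str, list[np.ndarray]] = defaultdict(list)
    skipped = 0
    for rec in vcf:
        alts = rec.ALT
        if (
            len(alts) != 1
            or len(rec.REF) != 1
            or len(alts[0]) != 1
            or alts[0] not in "ACGT"
            or rec.REF not in "ACGT"
        ):
            skipped += 1
            continue
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gts = np.array(rec.genotypes, dtype=object)
        counts = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                counts[i] = GenotypeMatrix.MISSING
            else:
                counts[i] = int(a > 0) + int(b > 0)
        pos_by_chrom[rec.CHROM].append(rec.POS - 1)
        geno_by_chrom[rec.CHROM].append(counts)
    if skipped:
        logger.info("parse_genotypes: skipped %d non-biallelic/non-SNP records", skipped)
    data = {
        chrom: (
            np.asarray(pos_by_chrom[chrom], dtype=np.int64),
            np.vstack(geno_by_chrom[chrom]),
        )
        for chrom in pos_by_chrom
    }
    gm = GenotypeMatrix(samples, {s: pop_map[s] for s in samples}, data,
                        chrom_lengths=chrom_lengths)
    gm.n_skipped = skipped  # type: ignore[attr-defined]
    return gm


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as a minimal biallelic-SNP VCF 4.2."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if gm.chrom_lengths:
            for chrom, length in gm.chrom_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        else:
            for chrom in gm.chroms:
                pos, _ = gm.data[chrom]
                length = int(pos[-1]) + 1 if pos.size else 1
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples) + "\n"
        )
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", GenotypeMatrix.MISSING: "./."}
        for chrom in gm.chroms:
            pos, geno = gm.data[chrom]
            for i in range(pos.size):
                gts = "\t".join(gt_str[int(g)] for g in geno[i])
                fh.write(
                    f"{chrom}\t{pos[i] + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
                )


def parse_expression(
    path: str | Path, transcript_gene_map: str | Path | Mapping[str, str]
) -> ExpressionTable:
    """Read a TPM matrix (first column transcript_id, header of sample ids)
    plus a two-column transcript->gene TSV (or mapping)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        col = df.columns[df.isna().any(axis=0)][0]
        raise ParseError(f"{path}: missing TPM value at {row!r}/{col!r}")
    if not isinstance(transcript_gene_map, Mapping):
        m = pd.read_csv(transcript_gene_map, sep="\t", header=None,
                        names=["transcript_id", "gene_id"], comment="#")
        transcript_gene_map = dict(zip(m["transcript_id"], m["gene_id"]))
    return ExpressionTable(df, transcript_gene_map)


def write_expression(expr: ExpressionTable, tpm_path: str | Path,
                     map_path: str | Path) -> None:
    out = expr.tpm.copy()
    out.index.name = "transcript_id"
    out.to_csv(tpm_path, sep="\t")
    expr.tx2gene.rename_axis("transcript_id").to_csv(
        map_path, sep="\t", header=False
    )


def parse_bedgraph(path: str | Path) -> CoverageTrack:
    runs: dict[str, list[tuple[int, int, float]]] = defaultdict(list)
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise ParseError(
                    f"{path}:{lineno}: bedGraph needs 4 columns"
                )
            runs[cols[0]].append((int(cols[1]), int(cols[2]), float(cols[3])))
    return CoverageTrack(runs)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, depths = track.runs[chrom]
            for s, e, d in zip(starts, ends, depths):
                fh.write(f"{chrom}\t{s}\t{e}\t{d:g}\n")


def parse_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, length = line.split()[:2]
            sizes[chrom] = int(length)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def parse_popmap(path: str | Path) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            sample, pop = line.split()[:2]
            out[sample] = pop
    return out


def parse_dnds(path: str | Path) -> dict[str, float]:
    """Two-column TSV gene_id -> dN/dS ratio."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "dnds"],
                     comment="#")
    return dict(zip(df["gene_id"], df["dnds"].astype(float)))
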
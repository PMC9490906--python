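"""Readers/writers for the standard formats the pipeline touches.

One coordinate convention everywhere: internal intervals are 0-based
half-open.  GTF (1-based inclusive) is shifted on read and restored on
write; BED is already half-open and passes through; VCF POS (1-based) is
shifted by one.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from spikelnc.models import (
    MISSING,
    GenomicInterval,
    Site,
    TranscriptModel,
    VariantPanel,
)

log = logging.getLogger(__name__)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')
_GFF3_ATTR_RE = re.compile(r"(\w+)=([^;]+)")


class ParseError(ValueError):
    pass


def _parse_attributes(field: str) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(field))
    if not attrs:  # GFF3-style key=value attributes
        attrs = dict(_GFF3_ATTR_RE.findall(field))
        # normalise GFF3 Parent/ID to GTF-ish keys
        if "transcript_id" not in attrs and "Parent" in attrs:
            attrs["transcript_id"] = attrs["Parent"]
        if "gene_id" not in attrs and "ID" in attrs:
            attrs.setdefault("gene_id", attrs["Parent"] if "Parent" in attrs else attrs["ID"])
    return attrs


def read_gtf(path) -> list[TranscriptModel]:
    """Assemble TranscriptModels from the exon lines of a GTF/GFF3 file.

    Exon records lacking a transcript_id are rejected and logged; any
    malformed line raises :class:`ParseError` naming the line number.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    gene_of: dict[str, str] = {}
    rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            chrom, _src, feature, start, end, _score, strand, _frame, attr = fields
            if feature.lower() != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start_i > end_i:
                raise ParseError(f"{path}:{lineno}: start > end")
            attrs = _parse_attributes(attr)
            tid = attrs.get("transcript_id")
            if not tid:
                rejected += 1
                log.warning("%s:%d: exon without transcript_id rejected", path, lineno)
                continue
            gene_of.setdefault(tid, attrs.get("gene_id", tid))
            # GTF 1-based inclusive -> 0-based half-open
            exons.setdefault(tid, []).append(
                GenomicInterval(chrom, start_i - 1, end_i, strand)
            )
    transcripts = []
    for tid, exon_list in exons.items():
        exon_list = sorted(exon_list, key=lambda e: e.start)
        iv = GenomicInterval(
            exon_list[0].chrom,
            exon_list[0].start,
            exon_list[-1].end,
            exon_list[0].strand,
        )
        transcripts.append(
            TranscriptModel(
                transcript_id=tid, gene_id=gene_of[tid], interval=iv, exons=exon_list
            )
        )
    if rejected:
        log.info("read_gtf(%s): rejected %d exon records without transcript_id", path, rejected)
    return sorted(transcripts, key=lambda t: (t.chrom, t.interval.start, t.transcript_id))


def write_gtf(transcripts, path, source: str = "spikelnc") -> None:
    """Write transcripts as GTF exon lines (internal half-open -> 1-based inclusive)."""
    with open(path, "w") as fh:
        for t in sorted(transcripts, key=lambda t: (t.chrom, t.interval.start, t.transcript_id)):
            for e in t.exons:
                fh.write(
                    f"{e.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t"
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";\n'
                )


def read_bed(path) -> list[tuple[GenomicInterval, str]]:
    """Read BED3/4/6 intervals (already 0-based half-open, no shift).

    Records with start >= end are rejected and logged; unnamed records get
    auto-generated names ``region_<n>``.
    """
    out = []
    n = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: BED line with < 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                log.warning("%s: degenerate interval %s:%d-%d skipped", path, chrom, start, end)
                continue
            n += 1
            name = fields[3] if len(fields) >= 4 and fields[3] not in (".", "") else f"region_{n}"
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            out.append((GenomicInterval(chrom, start, end, strand), name))
    return out


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv, name in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def read_group_map(path) -> dict[str, str]:
    """Read the sample -> population-group TSV (header row: sample, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_vcf(path, group_map_path) -> VariantPanel:
    """Read bi-allelic SNPs from a VCF into a VariantPanel.

    Multi-allelic and indel records are skipped (count reported on the
    panel); phased genotypes and homozygotes populate the haplotype array.
    A VCF sample missing from the group map is a hard error.
    """
    groups = read_group_map(group_map_path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    unmapped = [s for s in samples if s not in groups]
    if unmapped:
        raise ValueError(f"VCF samples missing from group map: {unmapped}")
    sites, dosage_rows, hap_rows = [], [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            skipped += 1
            continue
        sites.append(
            Site(
                interval=GenomicInterval(var.CHROM, var.POS - 1, var.POS),
                ref=var.REF,
                alt=var.ALT[0],
            )
        )
        gts = var.genotypes  # [allele0, allele1, phased] per sample
        dos = np.empty(len(samples), dtype=np.int8)
        hap = np.full((len(samples), 2), MISSING, dtype=np.int8)
        for j, (a0, a1, *rest) in enumerate(gts):
            phased = bool(rest[0]) if rest else False
            if a0 < 0 or a1 < 0:
                dos[j] = MISSING
            else:
                dos[j] = a0 + a1
                if phased or a0 == a1:
                    hap[j, 0], hap[j, 1] = a0, a1
        dosage_rows.append(dos)
        hap_rows.append(hap)
    if not sites:
        geno = np.zeros((0, len(samples)), dtype=np.int8)
        haps = np.zeros((0, len(samples), 2), dtype=np.int8)
    else:
        geno = np.vstack(dosage_rows)
        haps = np.stack(hap_rows)
    return VariantPanel(
        sites=sites,
        samples=samples,
        genotypes=geno,
        sample_groups={s: groups[s] for s in samples},
        haplotypes=haps,
        skipped_records=skipped,
    )


def write_vcf(panel: VariantPanel, path) -> None:
    """Emit a minimal phased/unphased VCF 4.2 from a panel."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = sorted({s.interval.chrom for s in panel.sites})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.samples) + "\n")
        for i, site in enumerate(panel.sites):
            cells = []
            for j in range(panel.n_samples):
                if panel.haplotypes is not None and panel.haplotypes[i, j, 0] >= 0:
                    cells.append(f"{panel.haplotypes[i, j, 0]}|{panel.haplotypes[i, j, 1]}")
                elif panel.genotypes[i, j] == MISSING:
                    cells.append("./.")
                elif panel.genotypes[i, j] == 1:
                    cells.append("0/1")
                else:
                    a = "1" if panel.genotypes[i, j] == 2 else "0"
                    cells.append(f"{a}/{a}")
            fh.write(
                f"{site.interval.chrom}\t{site.interval.start + 1}\t.\t{site.ref}\t"
                f"{site.alt}\t.\tPASS\t.\tGT\t" + "\t".join(cells) + "\n"
            )


def read_expression(path) -> pd.DataFrame:
    """Read a features x samples FPKM matrix (TSV, first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative abundance values")
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicated feature or sample labels")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="feature_id", float_format="%.6g")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_table(path) -> pd.DataFrame:
    """Generic headered TSV reader (coding calls, binding sites, energies, hits)."""
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
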
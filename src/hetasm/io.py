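"""Readers and writers for the standard formats the pipeline speaks.

FASTA/FASTQ go through Biopython (gzip transparent), SAM through pysam.
VCF output is a minimal 4.2 dialect (CHROM POS ID REF ALT QUAL FILTER INFO
with DP/AD); GFF3 is parsed to 0-based half-open internal intervals.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import pysam
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .simulate import FastqRead


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[tuple[str, str]]:
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(path, records, width: int = 70) -> None:
    """records: iterable of (id, seq) or (id, seq, description-suffix)."""
    with _open_text(path, "wt") as fh:
        for rec in records:
            name, seq = rec[0], rec[1]
            desc = f" {rec[2]}" if len(rec) > 2 and rec[2] else ""
            fh.write(f">{name}{desc}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path) -> list[FastqRead]:
    out = []
    with _open_text(path) as fh:
        try:
            for name, seq, qual in FastqGeneralIterator(fh):
                out.append(FastqRead(name.split()[0], seq.upper(), qual))
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record ~{len(out) * 4 + 1} in {path}: {exc}")
    return out


def write_fastq(path, reads) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{r.qual}\n")


def write_paired_fastq(prefix, pairs) -> tuple[Path, Path]:
    p1, p2 = Path(f"{prefix}_1.fastq"), Path(f"{prefix}_2.fastq")
    write_fastq(p1, (a for a, _ in pairs))
    write_fastq(p2, (b for _, b in pairs))
    return p1, p2


# ---------------------------------------------------------------------------
# SAM


@dataclass
class SamRecord:
    """The SAM subset the pipeline uses: ungapped or soft-clipped matches."""

    qname: str
    flag: int
    rname: str
    pos: int  # 0-based
    mapq: int
    cigar: str
    seq: str
    qual: str = "*"

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & 16)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & 4)


def write_sam(path, references: list[tuple[str, int]], records: list[SamRecord]) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in references],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.qname
            a.flag = rec.flag
            if not rec.is_unmapped:
                a.reference_name = rec.rname
                a.reference_start = rec.pos
                a.cigarstring = rec.cigar
            a.mapping_quality = rec.mapq
            a.query_sequence = rec.seq
            if rec.qual != "*":
                a.query_qualities = pysam.qualitystring_to_array(rec.qual)
            out.write(a)


def read_sam(path) -> tuple[list[tuple[str, int]], list[SamRecord]]:
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        refs = [(name, fh.get_reference_length(name)) for name in fh.references]
        records = []
        for a in fh:
            records.append(
                SamRecord(
                    qname=a.query_name,
                    flag=a.flag,
                    rname=a.reference_name or "*",
                    pos=a.reference_start if a.reference_start is not None else -1,
                    mapq=a.mapping_quality,
                    cigar=a.cigarstring or "*",
                    seq=a.query_sequence or "*",
                    qual=pysam.array_to_qualitystring(a.query_qualities)
                    if a.query_qualities is not None
                    else "*",
                )
            )
    return refs, records


# ---------------------------------------------------------------------------
# GFF3


@dataclass
class GffFeature:
    seqid: str
    source: str
    type: str
    start: int  # 0-based half-open internally
    end: int
    strand: str
    attributes: dict[str, str] = field(default_factory=dict)
    line_number: int = 0


def read_gff3(path) -> list[GffFeature]:
    feats = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{ln}: expected 9 GFF3 columns, got {len(cols)}")
            try:
                start1, end1 = int(cols[3]), int(cols[4])
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-integer GFF3 coordinates")
            if start1 < 1 or end1 < start1:
                raise ValueError(f"{path}:{ln}: invalid interval {start1}..{end1}")
            attrs = {}
            for kv in cols[8].split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    attrs[k.strip()] = v.strip()
            feats.append(
                GffFeature(cols[0], cols[1], cols[2], start1 - 1, end1, cols[6], attrs, ln)
            )
    return feats


def write_gff3(path, features: list[GffFeature]) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items()) or "."
            fh.write(
                f"{f.seqid}\t{f.source}\t{f.type}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# VCF


def write_vcf(path, contigs: list[tuple[str, int]], records) -> None:
    """records: iterables of (chrom, pos0, ref, alts list, info dict)."""
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##INFO=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        for name, length in contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos0, ref, alts, info in records:
            info_s = ";".join(
                f"{k}={','.join(str(x) for x in v) if isinstance(v, (list, tuple)) else v}"
                for k, v in info.items()
            )
            fh.write(
                f"{chrom}\t{pos0 + 1}\t.\t{ref}\t{','.join(alts) or '.'}\t.\tPASS\t{info_s or '.'}\n"
            )
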
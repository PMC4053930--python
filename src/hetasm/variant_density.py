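"""Read mapping, SNV calling, per-scaffold SNV density, sex-linkage calls.

In a male with a neo-XY system, scaffolds from the ancestral-X portion of
the neo-X are hemizygous: they carry no allelic variation, so their SNV
density is theoretically zero (excluding sequencing errors) while diploid
scaffolds show the genome-wide heterozygosity.  Mapping an individual's
own reads back to its assembly and ranking scaffolds by SNVs/kbp therefore
separates putative ancestral-X scaffolds from the diploid background.

The built-in mapper is deliberately minimal plumbing: exact-seed,
ungapped-extension, best-hit (ties unmapped), with similarity and aligned
length-fraction filters.  Real-data users supply external SAM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kmers import _window_ints, encode_seq, revcomp
from .io import SamRecord


@dataclass
class Alignment:
    read_id: str
    ref: str
    pos: int  # 0-based start of the aligned part on the reference
    strand: str
    matches: int
    aligned_len: int
    read_length: int
    seq: str  # read sequence in reference orientation
    qual: str = ""
    clip_left: int = 0  # bases of the read clipped off the contig start

    @property
    def similarity(self) -> float:
        return self.matches / self.aligned_len if self.aligned_len else 0.0


class ReferenceIndex:
    """Exact seed index of an assembly: every seed-mer position."""

    def __init__(self, references: list[tuple[str, str]], seed_len: int = 21):
        if not references or all(len(s) == 0 for _, s in references):
            raise ValueError("empty assembly")
        self.seed_len = seed_len
        self.names = [n for n, _ in references]
        self.seqs = {n: s for n, s in references}
        self.codes = {n: encode_seq(s) for n, s in references}
        self.index: dict[int, list[tuple[str, int]]] = {}
        for name, codes in self.codes.items():
            ok = codes < 4
            ints = _window_ints(np.where(ok, codes, 0), seed_len)
            valid = (
                np.convolve(ok.astype(np.int32), np.ones(seed_len, dtype=np.int32), "valid")
                == seed_len
            )
            for pos in np.flatnonzero(valid):
                self.index.setdefault(int(ints[pos]), []).append((name, int(pos)))


def _pack_seed(codes, off, sl) -> int | None:
    val = 0
    for j in range(off, off + sl):
        c = codes[j]
        if c > 3:
            return None
        val = (val << 2) | int(c)
    return val


def _candidate_offsets(idx: ReferenceIndex, codes: np.ndarray) -> set[tuple[str, int]]:
    sl = idx.seed_len
    rl = len(codes)
    if rl < sl:
        return set()
    offsets = {0, max(0, (rl - sl) // 2), rl - sl}
    cands = set()
    for off in offsets:
        val = _pack_seed(codes, off, sl)
        if val is None:
            continue
        for name, pos in idx.index.get(val, []):
            cands.add((name, pos - off))
    return cands


def map_read(
    idx: ReferenceIndex,
    name: str,
    seq: str,
    qual: str = "",
    min_similarity: float = 0.9,
    min_length_fraction: float = 0.5,
) -> Alignment | None:
    """Best ungapped placement of a read, or None (unmapped / ambiguous)."""
    rl = len(seq)
    best: list[tuple[int, str, int, str]] = []  # (matches, ref, offset, strand)
    best_m = -1
    fwd_codes = encode_seq(seq)
    rc_codes = np.where(fwd_codes < 4, 3 - fwd_codes, fwd_codes)[::-1]
    for strand, codes in (("+", fwd_codes), ("-", rc_codes)):
        for ref, off in _candidate_offsets(idx, codes):
            ref_codes = idx.codes[ref]
            lo = max(0, off)
            hi = min(len(ref_codes), off + rl)
            if hi - lo <= 0:
                continue
            sub = codes[lo - off : hi - off]
            m = int(np.count_nonzero(sub == ref_codes[lo:hi]))
            if m > best_m:
                best_m = m
                best = [(m, ref, off, strand)]
            elif m == best_m:
                best.append((m, ref, off, strand))
    if not best or best_m < 0:
        return None
    distinct = {(r, o, st) for _, r, o, st in best}
    if len(distinct) > 1:
        return None  # ambiguous best hit
    m, ref, off, strand = best[0]
    lo = max(0, off)
    hi = min(len(idx.codes[ref]), off + rl)
    aligned_len = hi - lo
    if aligned_len / rl < min_length_fraction or m / aligned_len < min_similarity:
        return None
    oriented_seq = seq if strand == "+" else revcomp(seq)
    oriented_qual = qual if strand == "+" else qual[::-1]
    return Alignment(
        read_id=name,
        ref=ref,
        pos=lo,
        strand=strand,
        matches=m,
        aligned_len=aligned_len,
        read_length=rl,
        seq=oriented_seq,
        qual=oriented_qual,
        clip_left=lo - off,
    )


def map_reads(
    reads,
    assembly: list[tuple[str, str]],
    seed_len: int = 21,
    min_similarity: float = 0.9,
    min_length_fraction: float = 0.5,
) -> tuple[list["Alignment"], int]:
    """Map FastqRead-like records; returns (alignments, n_unmapped)."""
    idx = ReferenceIndex(assembly, seed_len=seed_len)
    out, unmapped = [], 0
    for r in reads:
        a = map_read(idx, r.name, r.seq, getattr(r, "qual", ""), min_similarity, min_length_fraction)
        if a is None:
            unmapped += 1
        else:
            out.append(a)
    return out, unmapped


def alignments_to_sam(alignments: list[Alignment]) -> list[SamRecord]:
    records = []
    for a in alignments:
        cig = []
        if a.clip_left:
            cig.append(f"{a.clip_left}S")
        cig.append(f"{a.aligned_len}M")
        tail = a.read_length - a.clip_left - a.aligned_len
        if tail:
            cig.append(f"{tail}S")
        records.append(
            SamRecord(
                qname=a.read_id,
                flag=16 if a.strand == "-" else 0,
                rname=a.ref,
                pos=a.pos,
                mapq=60,
                cigar="".join(cig),
                seq=a.seq,
                qual=a.qual or "*",
            )
        )
    return records


# ---------------------------------------------------------------------------
# SNV calling and density


@dataclass
class SiteCall:
    scaffold: str
    position: int  # 0-based
    ref_base: str
    allele_depths: dict[str, int]
    total_depth: int
    is_snv: bool


def pileup_counts(alignments: list[Alignment], assembly: list[tuple[str, str]]):
    """Per-scaffold (L, 4) base-count matrices from ungapped alignments."""
    lengths = {n: len(s) for n, s in assembly}
    mats = {n: np.zeros((ln, 4), dtype=np.int32) for n, ln in lengths.items()}
    for a in alignments:
        if a.ref not in mats:
            raise ValueError(f"alignment references unknown scaffold {a.ref!r}")
        codes = encode_seq(a.seq)[a.clip_left : a.clip_left + a.aligned_len]
        ok = codes < 4
        pos = np.arange(a.pos, a.pos + a.aligned_len)
        np.add.at(mats[a.ref], (pos[ok], codes[ok].astype(np.intp)), 1)
    return mats


def call_snvs(
    alignments: list[Alignment],
    assembly: list[tuple[str, str]],
    min_coverage: int = 10,
    min_alt_reads: int = 2,
    min_alt_fraction: float = 0.2,
) -> list[SiteCall]:
    """Pileup-based SNV calls.

    A site is an SNV iff total depth >= min_coverage and at least two
    alleles each have >= min_alt_reads reads making up >= min_alt_fraction
    of the depth (the heterozygote evidence rule standing in for genotype
    likelihoods).
    """
    mats = pileup_counts(alignments, assembly)
    seqs = dict(assembly)
    bases = "ACGT"
    calls = []
    for name in sorted(mats):
        mat = mats[name]
        depth = mat.sum(axis=1)
        n_alleles = (mat >= min_alt_reads).sum(axis=1)
        cand = np.flatnonzero(n_alleles >= 2)
        for pos in cand:
            row = mat[pos]
            d = int(depth[pos])
            passing = [
                i for i in range(4) if row[i] >= min_alt_reads and row[i] >= min_alt_fraction * d
            ]
            is_snv = d >= min_coverage and len(passing) >= 2
            calls.append(
                SiteCall(
                    scaffold=name,
                    position=int(pos),
                    ref_base=seqs[name][pos],
                    allele_depths={bases[i]: int(row[i]) for i in range(4) if row[i] > 0},
                    total_depth=d,
                    is_snv=is_snv,
                )
            )
    return calls


@dataclass
class ScaffoldVariantSummary:
    scaffold: str
    length: int  # non-N bases
    snv_count: int
    density: float  # SNVs per kbp
    classification: str = "unclassified"


def scaffold_snv_density(
    calls: list[SiteCall], assembly: list[tuple[str, str]]
) -> list[ScaffoldVariantSummary]:
    """SNVs/kbp per scaffold over non-N length, sorted by scaffold id."""
    counts: dict[str, int] = {}
    for c in calls:
        if c.is_snv:
            counts[c.scaffold] = counts.get(c.scaffold, 0) + 1
    out = []
    for name, seq in sorted(assembly):
        ln = len(seq) - seq.count("N")
        if ln == 0:
            raise ValueError(f"scaffold {name!r} has zero non-N length")
        n = counts.get(name, 0)
        out.append(ScaffoldVariantSummary(name, ln, n, n / (ln / 1000.0)))
    return out


def assembly_density(summaries: list[ScaffoldVariantSummary]) -> float:
    total_snv = sum(s.snv_count for s in summaries)
    total_len = sum(s.length for s in summaries)
    return total_snv / (total_len / 1000.0) if total_len else 0.0


def classify_sex_linked(
    summaries: list[ScaffoldVariantSummary],
    min_classify_length: int = 50_000,
    threshold_fraction: float = 0.1,
) -> list[ScaffoldVariantSummary]:
    """Flag putative hemizygous (ancestral-X-like) scaffolds.

    A scaffold is a hemizygous candidate iff it is at least
    min_classify_length long and its density is at most threshold_fraction
    times the median density of scaffolds of that length.  Shorter
    scaffolds are left unclassified_short.
    """
    import warnings

    long_densities = [s.density for s in summaries if s.length >= min_classify_length]
    if not long_densities:
        warnings.warn("no scaffold reaches min_classify_length; nothing classified")
        for s in summaries:
            s.classification = "unclassified_short"
        return summaries
    median = float(np.median(long_densities))
    cutoff = threshold_fraction * median
    for s in summaries:
        if s.length < min_classify_length:
            s.classification = "unclassified_short"
        elif s.density <= cutoff and median > 0:
            s.classification = "hemizygous_candidate"
        else:
            s.classification = "diploid"
    return summaries
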
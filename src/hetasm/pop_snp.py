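"""Pooled-population SNP calling, allele-morphism classes, region densities.

Pools of individuals are sequenced as one dataset and mapped to the
reference assembly (similarity >= 0.9, aligned length fraction >= 0.5).
A site is reported as a SNP when its depth is at least min_coverage and
some non-consensus allele is seen in at least required_variant_count reads
making up at least min_variant_frequency of the depth (6.25% = 1 chromosome
out of a 16-chromosome pool of 8 diploids).  Base calls contribute only if
their quality — and, with the neighborhood filter on, every base quality in
the centered window — reaches min_quality.

Morphism = number of alleles passing the count/frequency filter: sites can
be monomorphic (a single passing allele differing from the assembly
consensus), dimorphic, trimorphic or tetramorphic.  SNPs are partitioned
into exonic / intronic / intergenic by gene models with exon > intron >
intergenic precedence, and densities are per kbp of non-N bases of each
region class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import minimum_filter1d

from ._kmers import encode_seq
from .io import GffFeature
from .variant_density import Alignment

_MORPHISM = {1: "monomorphic", 2: "dimorphic", 3: "trimorphic", 4: "tetramorphic"}
_BASES = "ACGT"


@dataclass
class PooledSnpSite:
    scaffold: str
    position: int  # 0-based
    consensus: str
    alleles: dict[str, tuple[int, float, float]]  # base -> (count, frequency, mean qual)
    total_depth: int
    morphism: str
    region: str = "unassigned"

    @property
    def passing_alleles(self) -> list[str]:
        return sorted(self.alleles)


def _quality_mask(qual: str, min_quality: int, window_length: int, neighborhood: bool):
    q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16) - 33
    if not neighborhood:
        return q >= min_quality
    # window minimum clipped to the read bounds: out-of-read positions do
    # not disqualify a central base near the read end
    wmin = minimum_filter1d(q, size=window_length, mode="constant", cval=127)
    return (q >= min_quality) & (wmin >= min_quality)


def call_pooled_snps(
    alignments: list[Alignment],
    assembly: list[tuple[str, str]],
    window_length: int = 51,
    min_quality: int = 20,
    min_coverage: int = 20,
    required_variant_count: int = 3,
    min_variant_frequency: float = 0.0625,
    neighborhood_filter: bool = True,
) -> list[PooledSnpSite]:
    """Report SNP sites passing the pooled filter set (defaults above)."""
    if window_length % 2 == 0:
        raise ValueError(f"window_length must be odd to center a site, got {window_length}")
    seqs = dict(assembly)
    counts = {n: np.zeros((len(s), 4), dtype=np.int32) for n, s in assembly}
    qsums = {n: np.zeros((len(s), 4), dtype=np.int64) for n, s in assembly}
    for a in alignments:
        if a.ref not in counts:
            raise ValueError(f"alignment references unknown scaffold {a.ref!r}")
        codes = encode_seq(a.seq)[a.clip_left : a.clip_left + a.aligned_len]
        if a.qual:
            mask = _quality_mask(a.qual, min_quality, window_length, neighborhood_filter)
            mask = mask[a.clip_left : a.clip_left + a.aligned_len]
        else:
            mask = np.ones(len(codes), dtype=bool)
        q = (
            np.frombuffer(a.qual.encode("ascii"), dtype=np.uint8).astype(np.int64) - 33
        )[a.clip_left : a.clip_left + a.aligned_len] if a.qual else np.zeros(len(codes), dtype=np.int64)
        ok = mask & (codes < 4)
        pos = np.arange(a.pos, a.pos + a.aligned_len)
        np.add.at(counts[a.ref], (pos[ok], codes[ok].astype(np.intp)), 1)
        np.add.at(qsums[a.ref], (pos[ok], codes[ok].astype(np.intp)), q[ok])

    sites = []
    for name in sorted(counts):
        mat = counts[name]
        qs = qsums[name]
        depth = mat.sum(axis=1)
        enough = depth >= min_coverage
        # a site is worth inspecting if any allele reaches the count floor
        cand = np.flatnonzero(enough & ((mat >= required_variant_count).any(axis=1)))
        ref_seq = seqs[name]
        for pos in cand:
            row = mat[pos]
            d = int(depth[pos])
            consensus = ref_seq[pos]
            passing = {
                _BASES[i]: (
                    int(row[i]),
                    row[i] / d,
                    float(qs[pos, i] / row[i]) if row[i] else 0.0,
                )
                for i in range(4)
                if row[i] >= required_variant_count and row[i] / d >= min_variant_frequency
            }
            if not any(b != consensus for b in passing):
                continue
            sites.append(
                PooledSnpSite(
                    scaffold=name,
                    position=int(pos),
                    consensus=consensus,
                    alleles=passing,
                    total_depth=d,
                    morphism=_MORPHISM[len(passing)],
                )
            )
    return sites


def classify_morphism(site: PooledSnpSite) -> str:
    """Morphism class = number of passing alleles; monomorphic sites carry
    a single passing allele that differs from the consensus."""
    n = len(site.alleles)
    if n == 0:
        raise ValueError("site has no passing alleles; it should not have been called")
    if n == 1 and next(iter(site.alleles)) == site.consensus:
        raise ValueError("single passing allele equals the consensus; not a SNP site")
    return _MORPHISM[n]


# ---------------------------------------------------------------------------
# region annotation


@dataclass
class RegionDensityReport:
    snp_counts: dict[str, int]
    base_counts: dict[str, int]
    densities: dict[str, float] = field(default_factory=dict)
    overall_density: float = 0.0

    def __post_init__(self):
        self.densities = {
            r: self.snp_counts.get(r, 0) / (self.base_counts[r] / 1000.0)
            if self.base_counts.get(r)
            else 0.0
            for r in ("exonic", "intronic", "intergenic")
        }
        total_bases = sum(self.base_counts.values())
        self.overall_density = (
            sum(self.snp_counts.values()) / (total_bases / 1000.0) if total_bases else 0.0
        )


def annotate_regions(
    sites: list[PooledSnpSite],
    gene_models: list[GffFeature],
    assembly: list[tuple[str, str]],
) -> tuple[RegionDensityReport, list[PooledSnpSite]]:
    """Assign each SNP a region class and compute per-region densities.

    Precedence: exon > intron (inside a gene but not an exon) > intergenic.
    Base counts per class cover the non-N portion of the assembly, so the
    class counts partition both the SNPs and the assembled bases exactly.
    """
    lengths = {n: len(s) for n, s in assembly}
    # 0 intergenic, 1 intronic, 2 exonic
    cls = {n: np.zeros(ln, dtype=np.int8) for n, ln in lengths.items()}
    for ftype, code in (("gene", 1), ("mRNA", 1), ("exon", 2)):
        for f in gene_models:
            if f.type != ftype:
                continue
            if f.seqid not in cls:
                raise ValueError(f"GFF feature {f.type}@line {f.line_number}: unknown scaffold {f.seqid!r}")
            if f.end > lengths[f.seqid]:
                raise ValueError(
                    f"GFF feature {f.type}@line {f.line_number} ends at {f.end} "
                    f"beyond scaffold {f.seqid!r} length {lengths[f.seqid]}"
                )
            np.maximum.at(cls[f.seqid], np.arange(f.start, f.end), code)

    names = ["intergenic", "intronic", "exonic"]
    base_counts = {n: 0 for n in names}
    for name, seq in assembly:
        non_n = np.frombuffer(seq.encode(), dtype=np.uint8) != ord("N")
        for code, rname in enumerate(names):
            base_counts[rname] += int(np.count_nonzero(non_n & (cls[name] == code)))

    snp_counts = {n: 0 for n in names}
    for s in sites:
        s.region = names[cls[s.scaffold][s.position]]
        snp_counts[s.region] += 1
    return RegionDensityReport(snp_counts, base_counts), sites
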
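"""Truth-based evaluation of assemblies against simulated genomes.

These helpers exist because the simulator records complete truth (both
haplotypes, het sites, hemizygous intervals): assemblies can be scored by
exact sequence identity rather than by alignment heuristics.
"""

from __future__ import annotations

import numpy as np

from ._kmers import canonical_kmer_ints, encode_seq, iter_acgt_runs, revcomp
from .simulate import DiploidTruth


def _kmer_array(seqs, k: int) -> np.ndarray:
    """Sorted unique canonical packed k-mers of a sequence collection."""
    if k > 31:
        raise ValueError("evaluation k must be <= 31")
    chunks = []
    for s in seqs:
        for run in iter_acgt_runs(encode_seq(s)):
            ints = canonical_kmer_ints(run, k)
            if len(ints):
                chunks.append(ints)
    if not chunks:
        return np.empty(0, dtype=np.uint64)
    return np.unique(np.concatenate(chunks))


def _covered_mask(seq: str, asm: np.ndarray, k: int) -> np.ndarray:
    """Boolean per-position mask: inside a k-window whose k-mer is in asm."""
    n = len(seq)
    mask = np.zeros(n, dtype=bool)
    codes = encode_seq(seq)
    is_ok = codes < 4
    # run boundaries with explicit coordinates (robust to multi-N gaps)
    bounded = np.concatenate([[False], is_ok, [False]])
    starts = np.flatnonzero(bounded[1:] & ~bounded[:-1])
    ends = np.flatnonzero(~bounded[1:] & bounded[:-1])
    for start, end in zip(starts, ends):
        run = codes[start:end]
        ints = canonical_kmer_ints(run, k)
        if len(ints):
            present = np.isin(ints, asm)
            cov = np.convolve(present.astype(np.int32), np.ones(k, dtype=np.int32)) > 0
            mask[start:end] |= cov[: len(run)]
    return mask


def truth_base_coverage(truth: DiploidTruth, assembled_seqs, k: int = 25) -> float:
    """Fraction of haplotype-A positions covered by assembly k-mers.

    A position counts as covered when any k-mer window containing it, from
    either haplotype at that locus, appears in the assembled sequences
    (canonical form).  Both haplotypes are consulted because popping keeps
    one allele per heterozygous site; either allele demonstrates that the
    locus was assembled.
    """
    asm = _kmer_array(assembled_seqs, k)
    covered = 0
    total = 0
    for chrom, seq_a in truth.haplotype_A.items():
        n = len(seq_a)
        total += n
        hit = _covered_mask(seq_a, asm, k)
        seq_b = truth.haplotype_B.get(chrom)
        if seq_b is not None:
            hit |= _covered_mask(seq_b, asm, k)
        covered += int(hit.sum())
    return covered / total if total else 0.0


def locate_exact(truth: DiploidTruth, query: str):
    """Find a sequence in either haplotype, either strand.

    Returns (haplotype, chromosome, start, strand) of the first occurrence
    or None.  Positions are on that haplotype's own coordinates (identical
    to haplotype A's for diploid chromosomes; there are no indels).
    """
    for hap_name, hap in (("A", truth.haplotype_A), ("B", truth.haplotype_B)):
        for chrom, seq in hap.items():
            i = seq.find(query)
            if i >= 0:
                return hap_name, chrom, i, "+"
            i = seq.find(revcomp(query))
            if i >= 0:
                return hap_name, chrom, i, "-"
    return None


def popped_bubble_het_fraction(records, truth: DiploidTruth) -> float:
    """Fraction of popped simple bubbles whose branch differences all fall
    on truth heterozygous sites.

    For each popped record the retained branch is located exactly in one
    haplotype; mismatch positions against the discarded branch are mapped
    to genome coordinates and checked against the het-site table.
    """
    het = {(c, p) for c, p, _, _ in truth.het_sites}
    total = matched = 0
    for rec in records:
        if rec.rule_applied not in ("short_two_snv", "long_identity"):
            continue
        total += 1
        ret = rec.retained_branch.seq
        ok = False
        for disc in rec.discarded_branches:
            if len(disc.seq) != len(ret):
                continue
            diffs = [i for i, (a, b) in enumerate(zip(ret, disc.seq)) if a != b]
            loc = locate_exact(truth, ret)
            if loc is None or not diffs:
                continue
            _, chrom, start, strand = loc
            if strand == "+":
                positions = [start + d for d in diffs]
            else:
                positions = [start + len(ret) - 1 - d for d in diffs]
            if all((chrom, p) in het for p in positions):
                ok = True
        matched += ok
    return matched / total if total else 1.0


def hemizygous_recovery(
    truth: DiploidTruth, flagged_seqs, k: int = 25
) -> float:
    """Fraction of planted hemizygous bases covered by flagged scaffolds."""
    asm = _kmer_array(flagged_seqs, k)
    covered = total = 0
    for chrom, s, e in truth.hemizygous_intervals:
        seq = truth.haplotype_A[chrom][s:e]
        total += len(seq)
        covered += int(_covered_mask(seq, asm, k).sum())
    return covered / total if total else 1.0


def n50(lengths) -> int:
    """Smallest length L such that pieces >= L hold >= 50% of total bases."""
    lengths = sorted(lengths, reverse=True)
    total = sum(lengths)
    acc = 0
    for ln in lengths:
        acc += ln
        if 2 * acc >= total:
            return ln
    return 0
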
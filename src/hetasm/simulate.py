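"""Synthetic diploid genomes, sequencing libraries, and pooled populations.

The simulator emulates the data structure of a male beetle genome project:
a diploid genome with heterozygous SNVs, a hemizygous ancestral-X-like
chromosome present in a single copy, paired-end (forward-reverse) and
mate-pair (reverse-forward, with a forward-reverse chimera contaminant)
libraries, and pooled population sequencing with known allele frequencies.

Every read name encodes its truth of origin in a colon-delimited scheme::

    sim:<library>:<pair index>:<haplotype>:<chromosome>:<frag start>:<frag end>:<orient>:<flag>

where orient is ``FR`` or ``RF`` and flag is ``chimera`` or ``-``.  Mates
carry ``/1`` and ``/2`` suffixes.  This lets every downstream stage be
checked against truth without a separate alignment-truth file format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kmers import revcomp

_BASES = "ACGT"


@dataclass
class SimConfig:
    """Parameters of a simulated diploid genome.

    heterozygosity is the per-base probability of a heterozygous SNV on the
    diploid portion; hemizygous_fraction is the fraction of the genome
    present in one copy only, planted as a dedicated chromosome carried by
    haplotype A alone (the ancestral-X analogue in a male).
    """

    genome_length: int = 200_000
    heterozygosity: float = 0.005
    hemizygous_fraction: float = 0.0
    n_chromosomes: int = 2
    repeat_fraction: float = 0.0
    seed: int = 0
    repeat_unit_length: int = 500

    def validate(self) -> None:
        if self.genome_length < 1000:
            raise ValueError(f"genome_length must be >= 1000, got {self.genome_length}")
        if not 0 <= self.heterozygosity <= 0.1:
            raise ValueError(f"heterozygosity must be in [0, 0.1], got {self.heterozygosity}")
        if not 0 <= self.hemizygous_fraction < 1:
            raise ValueError(
                f"hemizygous_fraction must be in [0, 1), got {self.hemizygous_fraction}"
            )
        if self.n_chromosomes < 1:
            raise ValueError(f"n_chromosomes must be >= 1, got {self.n_chromosomes}")
        if self.hemizygous_fraction > 0 and self.n_chromosomes < 2:
            raise ValueError(
                "hemizygous_fraction > 0 requires n_chromosomes >= 2 "
                "(the hemizygous region occupies its own chromosome)"
            )
        if not 0 <= self.repeat_fraction < 1:
            raise ValueError(f"repeat_fraction must be in [0, 1), got {self.repeat_fraction}")


@dataclass
class DiploidTruth:
    """Both haplotypes of a simulated individual plus truth tables.

    haplotype_B lacks the hemizygous chromosome(s) entirely; elsewhere the
    haplotypes are identical except at het_sites (substitutions only), so
    the two haplotypes share coordinates base for base.
    """

    haplotype_A: dict[str, str]
    haplotype_B: dict[str, str]
    het_sites: list[tuple[str, int, str, str]]
    hemizygous_intervals: list[tuple[str, int, int]]

    @property
    def chromosomes(self) -> list[str]:
        return list(self.haplotype_A)

    def total_length(self) -> int:
        return sum(len(s) for s in self.haplotype_A.values())

    def hemizygous_length(self) -> int:
        return sum(e - s for _, s, e in self.hemizygous_intervals)


@dataclass
class LibrarySpec:
    """A sequencing library: insert geometry, depth, orientation contract.

    paired_end libraries emit forward-reverse pairs; mate_pair libraries
    emit reverse-forward pairs except for chimera_fraction, which are
    emitted as short-fragment forward-reverse contaminants (the unlabelled
    short-fragment fraction of a biotin mate-pair protocol).
    """

    kind: str = "paired_end"
    fragment_mean: int = 400
    fragment_sd: int = 40
    read_length: int = 100
    coverage: float = 40.0
    error_rate: float = 0.0
    chimera_fraction: float = 0.0
    base_quality: int = 35
    name: str = "lib"
    chimera_fragment_mean: int = 500
    chimera_fragment_sd: int = 50

    def validate(self) -> None:
        if self.kind not in ("paired_end", "mate_pair"):
            raise ValueError(f"kind must be paired_end or mate_pair, got {self.kind!r}")
        if not 0 <= self.chimera_fraction < 1:
            raise ValueError(f"chimera_fraction must be in [0, 1), got {self.chimera_fraction}")
        if self.kind == "paired_end" and self.chimera_fraction != 0:
            raise ValueError("chimera_fraction must be 0 for paired_end libraries")
        if self.read_length > self.fragment_mean:
            raise ValueError(
                f"read_length {self.read_length} exceeds fragment_mean {self.fragment_mean}"
            )
        if self.kind == "mate_pair" and self.fragment_mean <= 2 * self.read_length:
            raise ValueError("mate_pair libraries require fragment_mean > 2 * read_length")


@dataclass
class FastqRead:
    name: str
    seq: str
    qual: str


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(_BASES))[rng.integers(0, 4, n)])


def simulate_diploid_genome(config: SimConfig) -> DiploidTruth:
    """Generate a diploid genome per config; deterministic in config.seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    hemi_len = int(round(config.hemizygous_fraction * config.genome_length))
    n_hemi = 1 if hemi_len > 0 else 0
    n_auto = config.n_chromosomes - n_hemi
    auto_total = config.genome_length - hemi_len
    lengths = [auto_total // n_auto] * n_auto
    lengths[-1] += auto_total - sum(lengths)

    hap_a: dict[str, str] = {}
    repeat_unit = _random_seq(rng, config.repeat_unit_length) if config.repeat_fraction > 0 else ""

    def make_chrom(length: int) -> str:
        seq = list(_random_seq(rng, length))
        if config.repeat_fraction > 0:
            n_copies = int(round(config.repeat_fraction * length / config.repeat_unit_length))
            for _ in range(n_copies):
                pos = int(rng.integers(0, max(1, length - config.repeat_unit_length)))
                seq[pos : pos + config.repeat_unit_length] = repeat_unit
        return "".join(seq)

    for i, ln in enumerate(lengths):
        hap_a[f"chr{i + 1}"] = make_chrom(ln)
    hemi_intervals: list[tuple[str, int, int]] = []
    if n_hemi:
        name = f"chrX{''}"
        hap_a[name] = make_chrom(hemi_len)
        hemi_intervals.append((name, 0, hemi_len))

    hap_b: dict[str, str] = {}
    het_sites: list[tuple[str, int, str, str]] = []
    hemi_names = {c for c, _, _ in hemi_intervals}
    for chrom, seq in hap_a.items():
        if chrom in hemi_names:
            continue
        arr = list(seq)
        n_sites = rng.binomial(len(seq), config.heterozygosity)
        positions = np.sort(rng.choice(len(seq), size=n_sites, replace=False))
        for pos in positions:
            ref = arr[pos]
            alt = _BASES[(_BASES.index(ref) + int(rng.integers(1, 4))) % 4]
            arr[pos] = alt
            het_sites.append((chrom, int(pos), ref, alt))
        hap_b[chrom] = "".join(arr)

    return DiploidTruth(hap_a, hap_b, het_sites, hemi_intervals)


def _sample_fragment(rng, chroms, lengths, mean, sd, min_len):
    """Pick (chrom, start, frag_len) uniformly by sequence length."""
    weights = np.asarray(lengths, dtype=float)
    weights /= weights.sum()
    for _ in range(100):
        flen = int(round(rng.normal(mean, sd)))
        flen = max(min_len, flen)
        ci = int(rng.choice(len(chroms), p=weights))
        if lengths[ci] >= flen:
            start = int(rng.integers(0, lengths[ci] - flen + 1))
            return chroms[ci], start, flen
    raise ValueError("no chromosome long enough for the requested fragment length")


def _apply_errors(rng, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
    for i in hits:
        arr[i] = _BASES[(_BASES.index(arr[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(arr)


def _emit_pair(rng, lib, hap_label, chrom, seq, start, flen, orient, flag, name):
    frag = seq[start : start + flen]
    rl = lib.read_length
    if orient == "FR":
        r1, r2 = frag[:rl], revcomp(frag[-rl:])
    else:  # RF: reads point outward
        r1, r2 = revcomp(frag[:rl]), frag[-rl:]
    r1 = _apply_errors(rng, r1, lib.error_rate)
    r2 = _apply_errors(rng, r2, lib.error_rate)
    q = chr(33 + lib.base_quality) * rl
    base = f"sim:{lib.name}:{name}:{hap_label}:{chrom}:{start}:{start + flen}:{orient}:{flag}"
    return FastqRead(base + "/1", r1, q), FastqRead(base + "/2", r2, q)


def simulate_reads(
    truth: DiploidTruth, spec: LibrarySpec, seed: int
) -> list[tuple[FastqRead, FastqRead]]:
    """Draw read pairs alternately from both haplotypes.

    The number of pairs is coverage x len(haplotype_A) / (2 x read_length).
    Hemizygous chromosomes exist only on haplotype A, so pairs assigned to
    haplotype B fall on the diploid chromosomes alone.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    ref_len = truth.total_length()
    n_pairs = int(round(spec.coverage * ref_len / (2 * spec.read_length)))

    haps = {
        "A": (list(truth.haplotype_A), [len(s) for s in truth.haplotype_A.values()]),
        "B": (list(truth.haplotype_B), [len(s) for s in truth.haplotype_B.values()]),
    }
    pairs = []
    for i in range(n_pairs):
        hap = "A" if i % 2 == 0 else "B"
        seqs = truth.haplotype_A if hap == "A" else truth.haplotype_B
        chroms, lengths = haps[hap]
        if spec.kind == "mate_pair" and rng.random() < spec.chimera_fraction:
            chrom, start, flen = _sample_fragment(
                rng, chroms, lengths, spec.chimera_fragment_mean,
                spec.chimera_fragment_sd, spec.read_length,
            )
            pairs.append(
                _emit_pair(rng, spec, hap, chrom, seqs[chrom], start, flen, "FR", "chimera", i)
            )
            continue
        orient = "FR" if spec.kind == "paired_end" else "RF"
        chrom, start, flen = _sample_fragment(
            rng, chroms, lengths, spec.fragment_mean, spec.fragment_sd, spec.read_length
        )
        pairs.append(_emit_pair(rng, spec, hap, chrom, seqs[chrom], start, flen, orient, "-", i))
    return pairs


def parse_read_name(name: str) -> dict:
    """Decode the truth fields embedded in a simulated read name."""
    core = name.rsplit("/", 1)[0]
    parts = core.split(":")
    if len(parts) != 9 or parts[0] != "sim":
        raise ValueError(f"not a simulated read name: {name!r}")
    return {
        "library": parts[1],
        "pair_index": int(parts[2]),
        "haplotype": parts[3],
        "chromosome": parts[4],
        "fragment_start": int(parts[5]),
        "fragment_end": int(parts[6]),
        "orientation": parts[7],
        "chimera": parts[8] == "chimera",
    }


# ---------------------------------------------------------------------------
# pooled populations


@dataclass
class PoolSiteTruth:
    chromosome: str
    position: int
    consensus: str
    allele_counts: dict[str, int]

    @property
    def frequencies(self) -> dict[str, float]:
        total = sum(self.allele_counts.values())
        return {a: c / total for a, c in self.allele_counts.items()}


def simulate_population(
    config: SimConfig,
    n_individuals: int,
    snp_rate: float = 0.002,
    multi_allelic_sites: int = 0,
    seed: int = 0,
) -> tuple[list[DiploidTruth], str]:
    """Build a population of diploid individuals sharing one reference.

    Segregating sites are planted at snp_rate per base with population
    allele frequencies drawn uniformly from the possible chromosome counts;
    multi_allelic_sites additional sites carry three alleles.  Genotypes
    are drawn by sampling each of an individual's two chromosomes
    independently from the population allele pool.  Returns the individuals
    plus the reference label used for chromosome naming (individuals share
    haplotype-A coordinates by construction).
    """
    if n_individuals < 2:
        raise ValueError("a population needs >= 2 individuals")
    base_cfg = SimConfig(
        genome_length=config.genome_length,
        heterozygosity=0.0,
        hemizygous_fraction=0.0,
        n_chromosomes=config.n_chromosomes,
        repeat_fraction=config.repeat_fraction,
        seed=config.seed,
    )
    ref = simulate_diploid_genome(base_cfg)
    rng = np.random.default_rng(seed)
    n_chrom_copies = 2 * n_individuals

    # per-site population allele assignment, per chromosome copy
    sites: list[tuple[str, int, list[str]]] = []  # (chrom, pos, allele per copy)
    for chrom, seq in ref.haplotype_A.items():
        n_sites = rng.binomial(len(seq), snp_rate)
        for pos in np.sort(rng.choice(len(seq), size=n_sites, replace=False)):
            refb = seq[int(pos)]
            alt = _BASES[(_BASES.index(refb) + int(rng.integers(1, 4))) % 4]
            minor = int(rng.integers(1, n_chrom_copies))  # 1..2N-1 minor copies
            copies = [alt] * minor + [refb] * (n_chrom_copies - minor)
            rng.shuffle(copies)
            sites.append((chrom, int(pos), copies))
    first_chrom = next(iter(ref.haplotype_A))
    used = {(c, p) for c, p, _ in sites}
    seq0 = ref.haplotype_A[first_chrom]
    planted = 0
    while planted < multi_allelic_sites:
        pos = int(rng.integers(0, len(seq0)))
        if (first_chrom, pos) in used:
            continue
        used.add((first_chrom, pos))
        refb = seq0[pos]
        others = [b for b in _BASES if b != refb]
        a1, a2 = rng.choice(others, size=2, replace=False)
        third = max(4, n_chrom_copies // 4)
        copies = [a1] * third + [a2] * third + [refb] * (n_chrom_copies - 2 * third)
        rng.shuffle(copies)
        sites.append((first_chrom, pos, [str(a) for a in copies]))
        planted += 1
    sites.sort()

    individuals = []
    for ind in range(n_individuals):
        hap_a = {c: list(s) for c, s in ref.haplotype_A.items()}
        hap_b = {c: list(s) for c, s in ref.haplotype_A.items()}
        het = []
        for chrom, pos, copies in sites:
            a_allele = copies[2 * ind]
            b_allele = copies[2 * ind + 1]
            hap_a[chrom][pos] = a_allele
            hap_b[chrom][pos] = b_allele
            if a_allele != b_allele:
                het.append((chrom, pos, a_allele, b_allele))
        individuals.append(
            DiploidTruth(
                {c: "".join(s) for c, s in hap_a.items()},
                {c: "".join(s) for c, s in hap_b.items()},
                het,
                [],
            )
        )
    return individuals, first_chrom


def pool_truth_table(population: list[DiploidTruth]) -> list[PoolSiteTruth]:
    """Per-site allele counts across all 2N chromosomes of a population.

    Derived directly from the haplotype sequences, so it works for any
    population whose individuals share reference coordinates.
    """
    _check_shared_coordinates(population)
    ref = population[0]
    out = []
    for chrom in ref.haplotype_A:
        seqs = []
        for ind in population:
            seqs.append(np.frombuffer(ind.haplotype_A[chrom].encode(), dtype=np.uint8))
            seqs.append(np.frombuffer(ind.haplotype_B[chrom].encode(), dtype=np.uint8))
        mat = np.vstack(seqs)
        variable = np.flatnonzero((mat != mat[0]).any(axis=0))
        for pos in variable:
            col = mat[:, pos]
            alleles, counts = np.unique(col, return_counts=True)
            table = {chr(a): int(c) for a, c in zip(alleles, counts)}
            consensus = max(sorted(table), key=lambda a: table[a])
            out.append(PoolSiteTruth(chrom, int(pos), consensus, table))
    return out


def _check_shared_coordinates(population: list[DiploidTruth]) -> None:
    if len(population) < 2:
        raise ValueError("a pool needs >= 2 individuals")
    ref = population[0]
    for ind in population[1:]:
        if list(ind.haplotype_A) != list(ref.haplotype_A):
            raise ValueError("individuals do not share chromosome sets")
        for chrom in ref.haplotype_A:
            if len(ind.haplotype_A[chrom]) != len(ref.haplotype_A[chrom]):
                raise ValueError(f"coordinate mismatch on {chrom}: differing lengths")


def simulate_pool(
    population: list[DiploidTruth], spec: LibrarySpec, seed: int
) -> tuple[list[tuple[FastqRead, FastqRead]], list[PoolSiteTruth]]:
    """Pooled sequencing of a population: reads drawn uniformly over all
    2N chromosomes, plus the realized per-site allele-frequency truth."""
    spec.validate()
    _check_shared_coordinates(population)
    truth_table = pool_truth_table(population)
    rng = np.random.default_rng(seed)
    ref_len = population[0].total_length()
    n_pairs = int(round(spec.coverage * ref_len / (2 * spec.read_length)))

    haplotypes = []
    for ind in population:
        haplotypes.append(ind.haplotype_A)
        haplotypes.append(ind.haplotype_B)
    chroms = list(population[0].haplotype_A)
    lengths = [len(population[0].haplotype_A[c]) for c in chroms]

    pairs = []
    for i in range(n_pairs):
        h = int(rng.integers(0, len(haplotypes)))
        chrom, start, flen = _sample_fragment(
            rng, chroms, lengths, spec.fragment_mean, spec.fragment_sd, spec.read_length
        )
        label = f"P{h // 2}{'A' if h % 2 == 0 else 'B'}"
        pairs.append(
            _emit_pair(
                rng, spec, label, chrom, haplotypes[h][chrom], start, flen,
                "FR" if spec.kind == "paired_end" else "RF", "-", i,
            )
        )
    return pairs, truth_table
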
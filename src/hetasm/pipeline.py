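"""End-to-end pipeline: simulate -> assemble -> pop bubbles -> filter mate
pairs -> scaffold -> merge transcripts -> sex scan (-> pooled SNPs).

All stage parameters live in a single PipelineConfig that round-trips
through YAML/JSON; unknown keys are rejected so stale configs fail loudly.
All randomness flows from the configured seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import bubbles as bb
from . import dbg, io, scaffolder, variant_density as vd
from .evaluate import n50
from .simulate import LibrarySpec, SimConfig, simulate_diploid_genome, simulate_reads

log = logging.getLogger("hetasm")


@dataclass
class AssemblyParams:
    k: int = 25
    min_multiplicity: int = 2
    max_bubble_interior: int = 64
    min_identity: float = 90.0


@dataclass
class ScaffoldParams:
    # the real-data defaults: s=500/n=10 (paired-end), s=1100/n=25 (6 kbp
    # mate-pair), s=3400/n=3 (10-12 kbp mate-pair); configure per library
    s: int = 1100
    n: int = 25


@dataclass
class SexScanParams:
    min_coverage: int = 10
    min_classify_length: int = 50_000
    threshold_fraction: float = 0.1


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    pe_library: LibrarySpec = field(default_factory=lambda: LibrarySpec(
        kind="paired_end", fragment_mean=400, fragment_sd=40, coverage=40.0, name="pe400"
    ))
    mp_library: LibrarySpec = field(default_factory=lambda: LibrarySpec(
        kind="mate_pair", fragment_mean=6000, fragment_sd=600, coverage=20.0,
        chimera_fraction=0.3, name="mp6k",
    ))
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    pe_scaffold: ScaffoldParams = field(default_factory=lambda: ScaffoldParams(s=500, n=10))
    mp_scaffold: ScaffoldParams = field(default_factory=lambda: ScaffoldParams(s=1100, n=25))
    sexscan: SexScanParams = field(default_factory=SexScanParams)
    reads_seed: int = 1

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        def build(tp, d, path):
            fields = {f.name: f for f in dataclasses.fields(tp)}
            unknown = set(d) - set(fields)
            if unknown:
                raise ValueError(f"unknown config key(s) {sorted(unknown)} under {path or 'top level'}")
            kwargs = {}
            for name, val in d.items():
                ftype = fields[name].type
                sub = _SECTION_TYPES.get(name)
                kwargs[name] = build(sub, val, f"{path}.{name}" if path else name) if sub else val
            return tp(**kwargs)

        return build(cls, data, "")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTION_TYPES = {
    "sim": SimConfig,
    "pe_library": LibrarySpec,
    "mp_library": LibrarySpec,
    "assembly": AssemblyParams,
    "pe_scaffold": ScaffoldParams,
    "mp_scaffold": ScaffoldParams,
    "sexscan": SexScanParams,
}


def assemble(reads, k: int, min_multiplicity: int = 2, max_interior: int = 64,
             min_identity: float = 90.0):
    """Reads -> (contigs, popped records): graph build, unitig compaction,
    bubble popping / complex-bubble spanning on the contig graph."""
    graph = dbg.build_kmer_graph(reads, k, min_multiplicity)
    unitigs = dbg.assemble_unitigs(graph)
    cg = dbg.build_contig_graph(unitigs, graph)
    records = bb.process_bubbles(cg, k, max_interior=max_interior, min_identity=min_identity)
    contigs = [dbg.Contig(cid, seq, cov) for cid, seq, cov in bb.contigs_from_graph(cg)]
    return contigs, records


def pair_alignments(pairs, assembly, library="lib", **map_kwargs):
    """Map both mates of each simulated pair; emit PairAlignment records."""
    idx = vd.ReferenceIndex(assembly, seed_len=map_kwargs.pop("seed_len", 21))
    out = []
    for r1, r2 in pairs:
        a1 = vd.map_read(idx, r1.name, r1.seq, r1.qual, **map_kwargs)
        a2 = vd.map_read(idx, r2.name, r2.seq, r2.qual, **map_kwargs)
        out.append(
            scaffolder.PairAlignment(
                read_id=r1.name.rsplit("/", 1)[0],
                contig1=a1.ref if a1 else None,
                pos1=a1.pos if a1 else -1,
                strand1=a1.strand if a1 else ".",
                contig2=a2.ref if a2 else None,
                pos2=a2.pos if a2 else -1,
                strand2=a2.strand if a2 else ".",
                read_length=len(r1.seq),
                library=library,
            )
        )
    return out


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the full pipeline, writing artifacts and a JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    log.info("stage simulate: genome %d bp", config.sim.genome_length)
    truth = simulate_diploid_genome(config.sim)
    io.write_fasta(outdir / "truth_hapA.fasta", truth.haplotype_A.items())
    io.write_fasta(outdir / "truth_hapB.fasta", truth.haplotype_B.items())
    with open(outdir / "truth_het_sites.tsv", "w") as fh:
        fh.write("chromosome\tposition\tallele_A\tallele_B\n")
        for c, p, a, b in truth.het_sites:
            fh.write(f"{c}\t{p}\t{a}\t{b}\n")
    pe_pairs = simulate_reads(truth, config.pe_library, config.reads_seed)
    mp_pairs = simulate_reads(truth, config.mp_library, config.reads_seed + 1)
    io.write_paired_fastq(outdir / "pe", pe_pairs)
    io.write_paired_fastq(outdir / "mp", mp_pairs)
    summary["simulate"] = {
        "genome_length": truth.total_length(),
        "het_sites": len(truth.het_sites),
        "hemizygous_bases": truth.hemizygous_length(),
        "pe_pairs": len(pe_pairs),
        "mp_pairs": len(mp_pairs),
    }

    log.info("stage assemble: k=%d", config.assembly.k)
    reads = [r.seq for pair in pe_pairs for r in pair]
    contigs, records = assemble(
        reads,
        config.assembly.k,
        config.assembly.min_multiplicity,
        config.assembly.max_bubble_interior,
        config.assembly.min_identity,
    )
    io.write_fasta(
        outdir / "contigs.fasta",
        [(c.id, c.sequence, f"cov={c.mean_kmer_coverage:.1f}") for c in contigs],
    )
    io.write_fasta(
        outdir / "popped_branches.fasta",
        [
            (f"bubble{i:05d}|{r.rule_applied}|{r.identity or ''}|{br.cov:.1f}", br.seq)
            for i, r in enumerate(records)
            for br in r.discarded_branches
        ],
    )
    rule_counts: dict[str, int] = {}
    for r in records:
        rule_counts[r.rule_applied] = rule_counts.get(r.rule_applied, 0) + 1
    summary["assemble"] = {
        "contigs": len(contigs),
        "contig_n50": n50([c.length for c in contigs]),
        "bubbles_popped": rule_counts,
    }

    log.info("stage scaffold: mate-pair filtering and linking")
    contig_fa = [(c.id, c.sequence) for c in contigs]
    mp_aln = pair_alignments(mp_pairs, contig_fa, library=config.mp_library.name)
    kept, removed = scaffolder.filter_matepairs(mp_aln)
    sg = scaffolder.build_scaffold_graph(
        contig_fa, kept, config.mp_scaffold.s, config.mp_scaffold.n,
        config.mp_library.fragment_mean, kind="mate_pair", library=config.mp_library.name,
    )
    scaffolds = scaffolder.scaffold(sg)
    seqs = {c.id: c.sequence for c in contigs}
    scaffold_fa = [(s.id, s.sequence(seqs)) for s in scaffolds]
    io.write_fasta(outdir / "scaffolds.fasta", scaffold_fa)
    with open(outdir / "scaffolds.agp.tsv", "w") as fh:
        fh.write("object\tobject_start\tobject_end\tcomponent\torientation\tgap_after\n")
        for s in scaffolds:
            at = 0
            for cid, o, gap in s.parts:
                ln = len(seqs[cid])
                fh.write(f"{s.id}\t{at + 1}\t{at + ln}\t{cid}\t{o}\t{gap}\n")
                at += ln + gap
    summary["scaffold"] = {
        "mate_pairs_kept": len(kept),
        "mate_pairs_removed": len(removed),
        "links": len(sg.links),
        "scaffolds": len(scaffolds),
        "scaffold_n50": n50([len(s) for _, s in scaffold_fa]),
    }

    log.info("stage sexscan: SNV density per scaffold")
    pe_reads = [r for pair in pe_pairs for r in pair]
    alignments, unmapped = vd.map_reads(pe_reads, scaffold_fa)
    io.write_sam(
        outdir / "pe_on_scaffolds.sam",
        [(n, len(s)) for n, s in scaffold_fa],
        vd.alignments_to_sam(alignments),
    )
    calls = vd.call_snvs(alignments, scaffold_fa, min_coverage=config.sexscan.min_coverage)
    snvs = [c for c in calls if c.is_snv]
    io.write_vcf(
        outdir / "snvs.vcf",
        [(n, len(s)) for n, s in scaffold_fa],
        [
            (
                c.scaffold,
                c.position,
                c.ref_base,
                sorted(a for a in c.allele_depths if a != c.ref_base),
                {"DP": c.total_depth, "AD": [c.allele_depths[a] for a in sorted(c.allele_depths)]},
            )
            for c in snvs
        ],
    )
    summaries = vd.scaffold_snv_density(calls, scaffold_fa)
    summaries = vd.classify_sex_linked(
        summaries, config.sexscan.min_classify_length, config.sexscan.threshold_fraction
    )
    with open(outdir / "snv_density.tsv", "w") as fh:
        fh.write("scaffold\tlength\tsnv_count\tdensity_per_kbp\tclassification\n")
        for s in summaries:
            fh.write(f"{s.scaffold}\t{s.length}\t{s.snv_count}\t{s.density:.4f}\t{s.classification}\n")
    summary["sexscan"] = {
        "snvs": len(snvs),
        "unmapped_reads": unmapped,
        "overall_density_per_kbp": round(vd.assembly_density(summaries), 4),
        "hemizygous_candidates": sorted(
            s.scaffold for s in summaries if s.classification == "hemizygous_candidate"
        ),
    }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
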
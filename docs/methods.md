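# Methods

This note documents the models, rules and numerical choices behind
`hetasm`, and what the simulation-based tests do and do not demonstrate.

## The problem being modelled

A single diploid individual of a species with a neo-XY sex-chromosome
system is sequenced and assembled. Three features dominate the analysis:

1. **Allelic heterozygosity.** The two haplotypes differ at SNVs, so the
   de Bruijn graph contains bubbles where an otherwise linear path splits
   into two allelic branches. The goal is a haploid consensus: bubbles
   are collapsed to one branch, not phased.
2. **Hemizygosity.** The ancestral-X portion of the neo-X exists in one
   copy in a male. Its scaffolds carry no allelic SNVs — theoretically
   zero, excluding sequencing errors — while diploid scaffolds show the
   genome-wide heterozygosity. This contrast identifies sex-linked
   scaffolds without a linkage map.
3. **Library artefacts.** Mate-pair protocols contaminate libraries with
   short-fragment chimeras in the wrong (forward-reverse) orientation;
   using them for scaffolding would create false joins.

## Assembly model

*Graph.* Nodes are canonical k-mers (lexicographic minimum of a k-mer and
its reverse complement); edges exist only where a (k+1)-mer was observed.
K-mers below a multiplicity floor (default 2) are dropped: with
error-free simulated reads this floor only trims chromosome-end k-mers,
while with errors it removes most singleton artefacts. Odd k avoids
palindromic self-reverse-complement k-mers. Default k is 25 for
desk-scale genomes; 64 is the documented choice for real short-read data
of 76–150 bp.

*Unitigs.* Maximal non-branching paths, traversed from sorted k-mers so
output is deterministic and read-order independent. Unitig ends are then
connected in a doubled contig graph — nodes (contig, +) and (contig, −)
with mirror-symmetric edges — on which all bubble work happens.

*Bubble definition.* A pair (u, v) bounds a bubble when every path
leaving u stays inside an acyclic interior and reaches v, the interior
has no side entrances or exits, and at least two distinct u→v paths
exist. Simple = exactly two single-vertex branches with N⁺(u) = N⁻(v);
anything with internal branching is complex. `find_bubbles` enumerates
all such pairs (nested bubbles included, reported outermost-first) for
analysis; the pipeline acts on minimal bubbles found by frontier
expansion, innermost-first with re-scanning, because the exhaustive
enumeration is quadratic in contigs.

*Popping rules.* For simple bubbles with branch length (maximum of the
two) below 3k: pop iff the branches are equal-length and differ at ≤ 2
positions no more than k apart — SNVs separated by more than k form
separate bubbles and are popped individually. At ≥ 3k: pop iff global
alignment identity ≥ 90%. Identity is (L − d)/L where d is the unit-cost
(Levenshtein) edit distance and L = max branch length, i.e. the most
compact minimal-edit alignment; this choice is deterministic where
"matches / columns of some optimal alignment" is not, because co-optimal
alignments can pad different numbers of indel columns. The
higher-coverage branch always represents the bubble; coverage ties break
to the lexicographically smaller sequence. Discarded branches are never
lost: each pop is archived with its rule, identity and coverage.

*Complex bubbles.* The interior is replaced by source + N×L + sink where
L is the longest u→v path in interior bases, computed by DP over a
topological order. On the contig graph each junction overlaps by k−1
bases, so a path through interior contigs n₁..nₘ spans
Σ(len(nᵢ) − (k−1)) − (k−1) bases; non-positive spans are clamped to one N.

*Consequences at 0.5% heterozygosity.* Single SNVs give branches of
2k−1 < 3k (short rule). Two SNVs d ≤ k apart give branches of
2k−1+d < 3k (short rule); d > k gives ≥ 3k (long rule, identity ≈ 97%).
Only ≥ 3 SNVs packed within ~k bases fail both rules and survive as
unpopped bubbles (a handful per 200 kbp), which later terminate scaffold
chains and are bridged by mate-pair links.

## Scaffolding

Orientation of a pair is observable only when both mates align to one
contig (left mate strand vs right mate strand: +/− is forward-reverse,
−/+ reverse-forward). Pairs bridging two contigs have no absolute
orientation against an unknown layout and pass the filter as
`undetermined` — removing them would discard exactly the evidence
scaffolding needs, while the chimeras being targeted are short fragments
that land on one contig.

Links aggregate pairs per oriented contig pair; contigs shorter than s
never enter the graph and links with fewer than n pairs are discarded.
The gap estimate is the mean over supporting pairs of (library fragment
mean − the two flank spans); negative estimates are clamped to a single N.
This estimator is a documented stand-in — the gap statistics of the
original scaffolder are not published. Chains stop at any contig end with
more than one link (conservative: ambiguity terminates rather than
guesses); cycles break at the lowest-count link. Every contig, linked or
not, appears in exactly one scaffold, so sequence is conserved.

Transcript merging: an expressed sequence spans two scaffolds when
consecutive alignment blocks (≥ 50 aligned bases each, within 10 kbp of
the facing scaffold edges — both defaults configurable) land on different
scaffolds. A junction needs ≥ 2 spanning transcripts from ≥ 2 distinct
libraries; merges insert exactly 100 Ns, apply transitively, and
conflicts resolve by support count then scaffold id.

## Read mapping (plumbing, not method)

The internal mapper is deliberately minimal: exact 21-mer seeds at three
read offsets, ungapped extension, best hit by match count, ties →
unmapped, then similarity ≥ 0.9 and aligned-length fraction ≥ 0.5
filters. It exists so the pipeline is self-contained on simulated data;
real-data users supply external SAM. Known limitation: a read whose every
seed window covers a variant cluster goes unmapped (~0.1% of reads at
0.5% heterozygosity), which slightly depresses mate-pair filter recall
when mapping against a heterozygous assembly.

## SNV density and sex-linkage

Pileup over ungapped alignments; a site is an SNV iff depth ≥ 10 and a
second allele has ≥ 2 reads making ≥ 20% of the depth. The evidence rule
substitutes for unpublished genotype-likelihood internals and is
configurable. Density is SNVs per kbp of non-N scaffold length.
Classification: scaffolds at least `min_classify_length` long with
density ≤ `threshold_fraction` (default 0.1) × the median density of
long scaffolds are hemizygous candidates. No absolute density threshold
is defensible across datasets, hence the relative rule. The 50 kbp
default length floor targets real assemblies; desk-scale runs on 200 kbp
simulated genomes use 10 kbp, chosen from the simulation design (the
planted hemizygous chromosome is 40 kbp and diploid scaffolds of 10 kbp
carry ~50 expected SNVs, so the two classes cannot overlap by chance).

The heterozygosity estimate is total SNVs on diploid-classified
scaffolds / total diploid length — i.e. a length-weighted mean density —
divided by 1000 to give a per-base rate.

## Pooled SNPs

Depth and allele counts accumulate only from base calls at quality ≥ 20;
with the neighborhood filter on (default), a call contributes only if
every base of the centered 51-base window that lies within the read also
meets the floor. The exact neighborhood semantics of the original
commercial caller are unpublished; this implementation is the documented
substitute and can be switched off. Allele frequency uses total site
depth as denominator. An allele passes with count ≥ 3 and frequency
≥ 6.25% (= 1 chromosome of 16 in a pool of eight diploids); a site is
reported when a passing allele differs from the assembly consensus.
Morphism = number of passing alleles; a monomorphic site's single passing
allele differs from the consensus (the pool is fixed for a non-reference
base). Regions use exon > intron > intergenic precedence over half-open
intervals parsed from 1-based GFF3; region base counts partition the
non-N assembly exactly, so densities are comparable across classes.

## Simulator: what it does and does not emulate

Genomes are i.i.d. uniform ACGT with optional exact 500 bp repeat
insertions; heterozygous variants are substitutions only, at a per-base
rate (default 0.5%); the hemizygous region is a dedicated chromosome
carried by haplotype A only, which matches the biology of a separate
ancestral-X and keeps hemizygous/diploid boundaries out of scaffold
interiors. Paired-end fragments are Normal(400, 40) by default,
mate-pair Normal(6000, 600) with a configurable chimera fraction emitted
as Normal(500, 50) forward-reverse pairs. Qualities are constant
(default Q35) so the SNP caller's quality filters are controllable;
errors, when enabled, are uniform substitutions. Read pairs alternate
haplotypes, so diploid loci receive balanced allelic coverage and the
hemizygous chromosome receives about half depth — as in a real male X.

Not emulated: indels and structural variation, GC-biased coverage,
position-dependent error profiles, diverged (non-identical) repeats.
Passing tests therefore demonstrate the correctness of the rules and
their interactions, not robustness to real-data noise; in particular the
assembler sees fewer spurious k-mers than real data would produce, and
the mapper is never stressed by indels.

## Problem sizes and determinism

Tests and the acceptance script run 200 kbp genomes at 40× (assembly,
sex scan; ten genomes in the test suite, three in the script), 50 kbp
at 40× across 20 seeds (heterozygosity recovery), and 20 kbp pools of
8 individuals at 200× (SNP calling) — sizes chosen so the full suite
completes in minutes on one CPU while keeping ≥ 500 expected
heterozygous sites per assembly run and ~40 segregating pool sites.
All randomness flows from explicit seeds through numpy Generators; dict
iteration is never relied on for order, and unitig/scaffold output is
sorted, so repeated runs are byte-identical.

## Known limitations

- Inverted-repeat structures that make a bubble's source the mirror of
  its sink are not resolved (left untouched by the popping pass).
- The frontier bubble scan bounds interiors at 64 vertices; larger tangles
  are left to scaffolding.
- Scaffold gap estimates ignore read-length corrections inside flanks and
  are means, not robust estimators; grossly discordant pairs are not
  trimmed before averaging.
- The SNV caller has no base-quality model (simulated qualities are
  constant) and calls substitutions only.
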
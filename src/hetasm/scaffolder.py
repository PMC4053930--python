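"""Mate-pair orientation filtering, s/n scaffolding, and transcript merging.

Mate-pair protocols contaminate libraries with short-fragment chimeras
that align forward-reverse instead of the expected reverse-forward; these
are removed before scaffolding.  Contigs of at least s bases are linked
when at least n filtered pairs support the same oriented junction, and
maximal unambiguous chains become scaffolds with N gaps.  Scaffold pairs
spanned by at least two expressed sequences from two different cDNA
libraries are merged across a fixed 100-N gap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from ._kmers import revcomp

log = logging.getLogger(__name__)


@dataclass
class PairAlignment:
    """Placements of the two mates of a read pair on a draft assembly.

    Positions are 0-based alignment starts; strands are '+'/'-'.  Unmapped
    mates have contig None.
    """

    read_id: str
    contig1: str | None
    pos1: int
    strand1: str
    contig2: str | None
    pos2: int
    strand2: str
    read_length: int
    library: str = "lib"

    @property
    def orientation(self) -> str:
        """Implied pair orientation.

        Only pairs with both mates on one contig have an absolute
        orientation; pairs bridging two contigs are 'undetermined' because
        their orientation depends on the unknown contig layout.
        """
        if self.contig1 is None or self.contig2 is None:
            return "unaligned"
        if self.contig1 != self.contig2:
            return "undetermined"
        if self.pos1 <= self.pos2:
            left, right = self.strand1, self.strand2
        else:
            left, right = self.strand2, self.strand1
        if (left, right) == ("+", "-"):
            return "forward_reverse"
        if (left, right) == ("-", "+"):
            return "reverse_forward"
        return "other"


def filter_matepairs(pairs) -> tuple[list[PairAlignment], list[tuple[PairAlignment, str]]]:
    """Partition a mate-pair stream into (kept, removed-with-reason).

    Forward-reverse pairs (short-fragment chimeras) and incoherent
    orientations are removed; reverse-forward pairs are kept, as are
    contig-bridging pairs whose orientation is unobservable.
    """
    kept, removed = [], []
    for p in pairs:
        o = p.orientation
        if o in ("reverse_forward", "undetermined"):
            kept.append(p)
        else:
            removed.append((p, o))
    return kept, removed


@dataclass
class ScaffoldLink:
    contig_a: str
    orient_a: str
    contig_b: str
    orient_b: str
    count: int
    gap_estimate: float
    library: str = "lib"

    @property
    def key(self):
        return (self.contig_a, self.orient_a, self.contig_b, self.orient_b)


@dataclass
class ScaffoldGraph:
    contig_lengths: dict[str, int]
    links: list[ScaffoldLink]
    s: int
    n: int


def _flip(o: str) -> str:
    return "-" if o == "+" else "+"


def _as_left_mate(kind, contig, pos, strand, rl, clen):
    """(orientation, flank) of a contig if this mate is the fragment's
    left end, under the library's orientation contract."""
    inner = "-" if kind == "mate_pair" else "+"  # strand of a left mate on a forward contig
    if strand == inner:
        return "+", clen - pos
    return "-", pos + rl


def _as_right_mate(kind, contig, pos, strand, rl, clen):
    inner = "+" if kind == "mate_pair" else "-"
    if strand == inner:
        return "+", pos + rl
    return "-", clen - pos


def build_scaffold_graph(
    contigs,
    pairs: list[PairAlignment],
    s: int,
    n: int,
    fragment_mean: int,
    kind: str = "mate_pair",
    library: str = "lib",
) -> ScaffoldGraph:
    """Aggregate pair evidence into oriented contig links.

    contigs: iterable of (id, sequence) or objects with .id/.sequence.
    Contigs shorter than s never enter the graph; links supported by fewer
    than n pairs are discarded.  The gap estimate is the mean over
    supporting pairs of fragment_mean minus the two flank spans.
    """
    if s < 0 or n < 1:
        raise ValueError("require s >= 0 and n >= 1")
    lengths = {}
    for c in contigs:
        if isinstance(c, tuple):
            lengths[c[0]] = len(c[1])
        else:
            lengths[c.id] = len(c.sequence)
    eligible = {cid for cid, ln in lengths.items() if ln >= s}

    acc: dict[tuple, list[float]] = {}
    for p in pairs:
        if p.contig1 is None or p.contig2 is None or p.contig1 == p.contig2:
            continue
        if p.contig1 not in eligible or p.contig2 not in eligible:
            continue
        oa, flank_a = _as_left_mate(kind, p.contig1, p.pos1, p.strand1, p.read_length, lengths[p.contig1])
        ob, flank_b = _as_right_mate(kind, p.contig2, p.pos2, p.strand2, p.read_length, lengths[p.contig2])
        key = (p.contig1, oa, p.contig2, ob)
        mirror = (p.contig2, _flip(ob), p.contig1, _flip(oa))
        if mirror < key:
            key = mirror
        acc.setdefault(key, []).append(float(fragment_mean - flank_a - flank_b))
    links = [
        ScaffoldLink(*key, count=len(gaps), gap_estimate=sum(gaps) / len(gaps), library=library)
        for key, gaps in sorted(acc.items())
        if len(gaps) >= n
    ]
    return ScaffoldGraph(lengths, links, s, n)


@dataclass
class Scaffold:
    id: str
    parts: list[tuple[str, str, int]]  # (contig id, orientation, gap_after in Ns; 0 for last)

    def sequence(self, contig_seqs: dict[str, str]) -> str:
        chunks = []
        for cid, o, gap in self.parts:
            seq = contig_seqs[cid] if o == "+" else revcomp(contig_seqs[cid])
            chunks.append(seq)
            if gap:
                chunks.append("N" * gap)
        return "".join(chunks)


def scaffold(graph: ScaffoldGraph) -> list[Scaffold]:
    """Chain contigs along unambiguous links.

    A contig end with more than one link terminates its chain; cycles are
    broken at their lowest-count link.  Every contig — linked, short, or
    isolated — appears in exactly one scaffold.
    """
    g = nx.DiGraph()
    link_by_edge = {}
    for lk in graph.links:
        a, b = (lk.contig_a, lk.orient_a), (lk.contig_b, lk.orient_b)
        ma, mb = (lk.contig_b, _flip(lk.orient_b)), (lk.contig_a, _flip(lk.orient_a))
        g.add_edge(a, b, count=lk.count, gap=lk.gap_estimate)
        g.add_edge(ma, mb, count=lk.count, gap=lk.gap_estimate)
        link_by_edge[(a, b)] = lk
        link_by_edge[(ma, mb)] = lk

    # break cycles at the weakest link
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        edge = min(cycle, key=lambda e: (g.edges[e[0], e[1]]["count"], str(e)))
        lk = link_by_edge.get((edge[0], edge[1]))
        log.warning("breaking scaffold link cycle at %s (count=%d)", edge, g.edges[edge[0], edge[1]]["count"])
        a, b = edge[0], edge[1]
        ma, mb = (b[0], _flip(b[1])), (a[0], _flip(a[1]))
        g.remove_edge(a, b)
        if g.has_edge(ma, mb):
            g.remove_edge(ma, mb)

    def next_node(x):
        succs = list(g.successors(x))
        if len(succs) != 1:
            return None
        y = succs[0]
        if g.in_degree(y) != 1 or y[0] == x[0]:
            return None
        return y

    chains = []
    used: set[str] = set()
    for start in sorted(g.nodes):
        if start[0] in used:
            continue
        # walk backward to the chain head
        head = start
        seen = {head[0]}
        while True:
            preds = [p for p in g.predecessors(head) if next_node(p) == head]
            if len(preds) != 1 or preds[0][0] in seen or preds[0][0] in used:
                break
            head = preds[0]
            seen.add(head[0])
        chain = [head]
        cur = head
        while True:
            nxt = next_node(cur)
            if nxt is None or nxt[0] in used or any(nxt[0] == c[0] for c in chain):
                break
            chain.append(nxt)
            cur = nxt
        mirror = [(cid, _flip(o)) for cid, o in reversed(chain)]
        if mirror < chain:
            chain = mirror
        chains.append(chain)
        used.update(cid for cid, _ in chain)

    for cid in sorted(graph.contig_lengths):
        if cid not in used:
            chains.append([(cid, "+")])
            used.add(cid)

    chains.sort(key=lambda ch: (ch[0][0], [c[0] for c in ch]))
    scaffolds = []
    for i, chain in enumerate(chains):
        parts = []
        for j, (cid, o) in enumerate(chain):
            gap = 0
            if j + 1 < len(chain):
                est = g.edges[chain[j], chain[j + 1]]["gap"]
                gap = max(int(round(est)), 1)
            parts.append((cid, o, gap))
        scaffolds.append(Scaffold(id=f"scaffold{i:05d}", parts=parts))
    return scaffolds


# ---------------------------------------------------------------------------
# transcript-evidence merging


@dataclass
class TranscriptAlignment:
    """One spliced-alignment block of an expressed sequence on a scaffold."""

    transcript_id: str
    library: str
    scaffold_id: str
    start: int  # 0-based on scaffold
    end: int
    strand: str
    tstart: int  # position of the block on the transcript
    tend: int


def merge_by_transcripts(
    scaffolds: list[Scaffold],
    scaffold_seqs: dict[str, str],
    alignments: list[TranscriptAlignment],
    min_support: int = 2,
    min_libraries: int = 2,
    min_aligned: int = 50,
    edge_distance: int = 10_000,
    gap: int = 100,
) -> tuple[list[Scaffold], dict[str, str]]:
    """Merge scaffold pairs spanned by expressed-sequence evidence.

    A merge needs >= min_support spanning transcripts from >= min_libraries
    distinct libraries agreeing on the same oriented junction; merged
    scaffolds are joined across exactly `gap` Ns.  Returns new scaffolds
    (parts reference merged-scaffold pseudo-contigs) and their sequences.
    """
    by_transcript: dict[str, list[TranscriptAlignment]] = {}
    for a in alignments:
        by_transcript.setdefault(a.transcript_id, []).append(a)

    evidence: dict[tuple, set[tuple[str, str]]] = {}
    for tid, blocks in sorted(by_transcript.items()):
        blocks = sorted(blocks, key=lambda b: b.tstart)
        for b1, b2 in zip(blocks, blocks[1:]):
            if b1.scaffold_id == b2.scaffold_id:
                continue
            if b1.end - b1.start < min_aligned or b2.end - b2.start < min_aligned:
                continue
            len1 = len(scaffold_seqs[b1.scaffold_id])
            len2 = len(scaffold_seqs[b2.scaffold_id])
            face1 = "right" if b1.strand == "+" else "left"
            face2 = "left" if b2.strand == "+" else "right"
            near1 = (len1 - b1.end <= edge_distance) if face1 == "right" else (b1.start <= edge_distance)
            near2 = (b2.start <= edge_distance) if face2 == "left" else (len2 - b2.end <= edge_distance)
            if not (near1 and near2):
                continue
            key = (b1.scaffold_id, face1, b2.scaffold_id, face2)
            mkey = (b2.scaffold_id, face2, b1.scaffold_id, face1)
            if mkey < key:
                key = mkey
            evidence.setdefault(key, set()).add((tid, b1.library))

    qualified = []
    for key, support in sorted(evidence.items()):
        tids = {t for t, _ in support}
        libs = {l for _, l in support}
        if len(tids) >= min_support and len(libs) >= min_libraries:
            qualified.append((-len(tids), key))
    qualified.sort()

    face_used: set[tuple[str, str]] = set()
    joins = []
    for _, (sa, fa, sb, fb) in qualified:
        if (sa, fa) in face_used or (sb, fb) in face_used:
            continue
        face_used.update([(sa, fa), (sb, fb)])
        joins.append((sa, fa, sb, fb))

    # walk join chains; orientation set so joined faces meet
    jg: dict[tuple[str, str], tuple[str, str]] = {}
    for sa, fa, sb, fb in joins:
        jg[(sa, fa)] = (sb, fb)
        jg[(sb, fb)] = (sa, fa)

    sid_order = [s.id for s in scaffolds]
    merged_into: set[str] = set()
    out_chains: list[list[tuple[str, str]]] = []  # (scaffold id, orientation)
    for sid in sid_order:
        if sid in merged_into:
            continue
        if (sid, "left") not in jg and (sid, "right") not in jg:
            out_chains.append([(sid, "+")])
            merged_into.add(sid)
            continue
        # find the chain head: follow joins leftward from sid
        cur, face = sid, "left"
        seen = {sid}
        while (cur, face) in jg:
            nxt, nface = jg[(cur, face)]
            if nxt in seen:
                break
            cur, face = nxt, _other_face(nface)
            seen.add(cur)
        head, head_entry = cur, face  # head's free face is `face`
        chain = []
        cur = head
        orient = "+" if head_entry == "left" else "-"
        exit_face = "right" if orient == "+" else "left"
        seen = set()
        while True:
            chain.append((cur, orient))
            seen.add(cur)
            if (cur, exit_face) not in jg:
                break
            nxt, nface = jg[(cur, exit_face)]
            if nxt in seen:
                break
            cur = nxt
            orient = "+" if nface == "left" else "-"
            exit_face = "right" if orient == "+" else "left"
        out_chains.append(chain)
        merged_into.update(s for s, _ in chain)

    new_scaffolds, new_seqs = [], {}
    for i, chain in enumerate(out_chains):
        sid = f"merged{i:05d}" if len(chain) > 1 else chain[0][0]
        parts = []
        chunks = []
        for j, (s, o) in enumerate(chain):
            seq = scaffold_seqs[s] if o == "+" else revcomp(scaffold_seqs[s])
            chunks.append(seq)
            g_after = gap if j + 1 < len(chain) else 0
            if g_after:
                chunks.append("N" * g_after)
            parts.append((s, o, g_after))
        new_scaffolds.append(Scaffold(id=sid, parts=parts))
        new_seqs[sid] = "".join(chunks)
    return new_scaffolds, new_seqs


def _other_face(face: str) -> str:
    return "left" if face == "right" else "right"
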
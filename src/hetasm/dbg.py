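"""De Bruijn graph construction and unitig compaction.

The graph is strand-symmetric: a k-mer and its reverse complement are one
node, represented by the lexicographically smaller of the two (the
canonical form).  Edges exist only where a (k+1)-mer was observed in the
reads.  Unitigs are maximal non-branching paths, emitted in canonical
orientation and sorted by sequence so the output is independent of read
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from ._kmers import canonical, count_canonical_kmers, revcomp


@dataclass
class KmerGraph:
    k: int
    counts: dict[str, int]  # canonical k-mer -> multiplicity
    edges: set[str]  # canonical (k+1)-mers supporting adjacencies
    _adj: dict[str, list[str]] | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.counts)

    def oriented_adjacency(self) -> dict[str, list[str]]:
        """Successors of every oriented k-mer implied by the edge set.

        Keys and values are oriented k-mer strings (not necessarily
        canonical); an oriented k-mer absent from the dict has no
        successors.  Built once and cached.
        """
        if self._adj is None:
            # edges are guaranteed consistent with the node set by
            # build_kmer_graph, so no per-edge membership checks here
            adj: dict[str, list[str]] = {}
            for e in self.edges:
                for s in (e, revcomp(e)):
                    adj.setdefault(s[:-1], []).append(s[1:])
            for key, v in adj.items():
                if len(v) > 1:
                    adj[key] = sorted(set(v))
            self._adj = adj
        return self._adj

    def successors(self, oriented: str) -> list[str]:
        return self.oriented_adjacency().get(oriented, [])

    def predecessors(self, oriented: str) -> list[str]:
        return [revcomp(s) for s in self.successors(revcomp(oriented))]


@dataclass
class Contig:
    id: str
    sequence: str
    mean_kmer_coverage: float

    @property
    def length(self) -> int:
        return len(self.sequence)


def build_kmer_graph(reads, k: int, min_multiplicity: int = 2) -> KmerGraph:
    """Count canonical k-mers and (k+1)-mers from reads.

    K-mers spanning N are skipped; non-ACGTN characters raise.  K-mers with
    multiplicity below min_multiplicity are dropped, as are edges whose
    endpoint k-mers were dropped.
    """
    if k < 3:
        raise ValueError(f"k must be >= 3, got {k}")
    if min_multiplicity < 1:
        raise ValueError(f"min_multiplicity must be >= 1, got {min_multiplicity}")
    reads = [r if isinstance(r, str) else r.seq for r in reads]
    counts, shortest = count_canonical_kmers(reads, k)
    if reads and k > shortest:
        raise ValueError(f"k={k} exceeds shortest read length {shortest}")
    edge_counts, _ = count_canonical_kmers(reads, k + 1)
    counts = {km: c for km, c in counts.items() if c >= min_multiplicity}
    edges = {
        e
        for e in edge_counts
        if canonical(e[:-1]) in counts and canonical(e[1:]) in counts
    }
    return KmerGraph(k=k, counts=counts, edges=edges)


def assemble_unitigs(graph: KmerGraph) -> list[Contig]:
    """Compact the graph into maximal non-branching paths.

    Every k-mer ends up in exactly one unitig.  Traversal starts from
    sorted canonical k-mers and extension stops at any branch (out-degree
    != 1 of the current node or in-degree != 1 of the next), so the result
    is deterministic and read-order independent.
    """
    if not graph.counts:
        raise ValueError("empty k-mer graph")
    visited: set[str] = set()
    unitigs: list[tuple[str, float]] = []
    adj = graph.oriented_adjacency()
    indeg: dict[str, int] = {}
    for ts in adj.values():
        for t in ts:
            indeg[t] = indeg.get(t, 0) + 1
    empty: list[str] = []

    def extend(start: str) -> list[str]:
        """Oriented k-mers of the maximal unitig through `start` (forward)."""
        path = [start]
        in_path = {canonical(start)}
        cur = start
        while True:
            succs = adj.get(cur, empty)
            if len(succs) != 1:
                break
            nxt = succs[0]
            if indeg.get(nxt, 0) != 1:
                break
            c = canonical(nxt)
            if c in in_path or c in visited:
                break
            path.append(nxt)
            in_path.add(c)
            cur = nxt
        return path

    for km in sorted(graph.counts):
        if km in visited:
            continue
        fwd = extend(km)
        # extend backward = forward from the reverse complement
        bwd = extend(revcomp(km))
        path = [revcomp(s) for s in reversed(bwd)] + fwd[1:]
        visited.update(canonical(s) for s in path)
        seq = path[0] + "".join(s[-1] for s in path[1:])
        cov = sum(graph.counts[canonical(s)] for s in path) / len(path)
        seq = min(seq, revcomp(seq))
        unitigs.append((seq, cov))

    unitigs.sort()
    return [
        Contig(id=f"ctg{i:06d}", sequence=seq, mean_kmer_coverage=cov)
        for i, (seq, cov) in enumerate(unitigs)
    ]


def build_contig_graph(contigs: list[Contig], graph: KmerGraph) -> nx.DiGraph:
    """Adjacency of unitig ends under (k-1)-overlap, as a doubled digraph.

    Nodes are (contig id, '+') and (contig id, '-'); each node carries the
    oriented sequence and coverage.  An edge (a, oa) -> (b, ob) means the
    oa-oriented sequence of a is followed by the ob-oriented sequence of b
    with a (k-1)-base overlap supported by an observed (k+1)-mer.
    """
    k = graph.k
    g = nx.DiGraph(k=k, overlap=k - 1)
    start_lookup: dict[str, list[tuple[str, str]]] = {}
    for c in contigs:
        for orient, seq in (("+", c.sequence), ("-", revcomp(c.sequence))):
            g.add_node((c.id, orient), seq=seq, cov=c.mean_kmer_coverage)
            start_lookup.setdefault(seq[:k], []).append((c.id, orient))
    for c in contigs:
        for orient, seq in (("+", c.sequence), ("-", revcomp(c.sequence))):
            end_kmer = seq[-k:]
            for succ in graph.successors(end_kmer):
                for target in start_lookup.get(succ, []):
                    if target == (c.id, orient) and len(seq) == k:
                        continue  # self-loop of a single-k-mer unitig
                    g.add_edge((c.id, orient), target)
    return g
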
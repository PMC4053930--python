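"""Bubble detection and resolution in assembly graphs.

A bubble is a pair of vertices (u, v) such that every path leaving u
eventually passes through v, with at least two distinct u->v paths and an
acyclic interior.  Heterozygous SNVs create *simple* bubbles: exactly two
single-vertex branches where the out-neighborhood of u equals the
in-neighborhood of v.  Anything with internal branching is *complex*.

Resolution rules:

* simple, branch length < 3k: popped when the branches differ by at most
  two substitutions lying within k bases of each other; the
  highest-coverage branch represents the bubble, the other is archived.
* simple, branch length >= 3k: popped when the branches align globally at
  >= 90% identity (matches / alignment columns, minimal-edit alignment).
* complex: the interior is replaced by a span of Ns whose length is the
  longest path through the bubble.

Graphs are networkx DiGraphs whose nodes carry 'seq' and 'cov' attributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import networkx as nx


@dataclass
class Branch:
    nodes: tuple
    seq: str
    cov: float


@dataclass
class Bubble:
    source: object
    sink: object
    interior: frozenset
    kind: str  # 'simple' | 'complex'
    branches: list[Branch] = field(default_factory=list)
    n_paths: int = 0

    @property
    def nodes(self) -> set:
        return set(self.interior) | {self.source, self.sink}


@dataclass
class PoppedRecord:
    bubble_source: object
    bubble_sink: object
    retained_branch: Branch
    discarded_branches: list[Branch]
    rule_applied: str  # 'short_two_snv' | 'long_identity' | 'complex_span'
    identity: float | None = None


# ---------------------------------------------------------------------------
# detection


def _bubble_at(g: nx.DiGraph, u, v) -> Bubble | None:
    """Test the (u, v) pair against the bubble conditions."""
    if u == v:
        return None
    # interior candidates: nodes reachable from u without passing through v
    interior: set = set()
    stack = [s for s in g.successors(u)]
    reached_v = False
    while stack:
        x = stack.pop()
        if x == v:
            reached_v = True
            continue
        if x == u or x in interior:
            if x == u:
                return None  # cycle back to the source
            continue
        interior.add(x)
        stack.extend(g.successors(x))
    if not reached_v or not interior:
        return None
    closure = interior | {v}
    for x in interior:
        succ = set(g.successors(x))
        if not succ or not succ <= closure:
            return None  # dead end or escape: a path from u avoids v
        if not set(g.predecessors(x)) <= interior | {u}:
            return None  # side entrance into the bubble
    if not set(g.successors(u)) <= closure:
        return None
    if not nx.is_directed_acyclic_graph(g.subgraph(interior)):
        return None
    n_paths = _count_paths(g, u, v, interior)
    if n_paths < 2:
        return None

    simple = (
        len(interior) == 2
        and not g.has_edge(u, v)
        and all(
            set(g.predecessors(x)) == {u} and set(g.successors(x)) == {v}
            for x in interior
        )
    )
    b = Bubble(u, v, frozenset(interior), "simple" if simple else "complex", n_paths=n_paths)
    if simple:
        b.branches = sorted(
            (Branch((x,), g.nodes[x]["seq"], g.nodes[x]["cov"]) for x in interior),
            key=lambda br: br.seq,
        )
    return b


def _count_paths(g: nx.DiGraph, u, v, interior: set) -> int:
    """Distinct u->v paths through an acyclic interior (DAG DP), capped."""
    order = list(nx.topological_sort(g.subgraph(interior)))
    npaths = {u: 1}
    for x in [u] + order:
        base = npaths.get(x, 0)
        if not base:
            continue
        for y in g.successors(x):
            if y in interior or y == v:
                npaths[y] = min(npaths.get(y, 0) + base, 10**6)
    return npaths.get(v, 0)


def find_bubbles(
    g: nx.DiGraph, minimal_only: bool = False, max_interior: int = 64
) -> list[Bubble]:
    """Enumerate bubbles, outermost-first.

    With minimal_only=False every (u, v) pair satisfying the bubble
    conditions is reported, including nested and overlapping bubbles
    (quadratic; intended for modest graphs).  With minimal_only=True a
    frontier scan reports, for each branching vertex, only the nearest
    closing vertex — the form the assembly pipeline acts on — and bounds
    the interior at max_interior vertices.
    """
    bubbles = []
    if minimal_only:
        for u in g.nodes:
            if g.out_degree(u) < 2:
                continue
            v = _nearest_sink(g, u, max_interior)
            if v is None:
                continue
            b = _bubble_at(g, u, v)
            if b is not None:
                bubbles.append(b)
    else:
        for u in g.nodes:
            if g.out_degree(u) < 1:
                continue
            for v in nx.descendants(g, u):
                b = _bubble_at(g, u, v)
                if b is not None:
                    bubbles.append(b)
    bubbles.sort(key=lambda b: (-len(b.interior), str(b.source), str(b.sink)))
    return bubbles


def _nearest_sink(g: nx.DiGraph, u, max_interior: int):
    """Frontier expansion: grow the set of interior vertices
    until the frontier collapses to a single closing vertex."""
    visited: set = set()
    frontier = set(g.successors(u))
    while frontier:
        if len(frontier) == 1:
            (v,) = frontier
            if v != u and set(g.predecessors(v)) <= visited | {u}:
                return v
        if len(visited) > max_interior:
            return None
        expandable = [
            x
            for x in sorted(frontier, key=str)
            if x != u and set(g.predecessors(x)) <= visited | {u}
        ]
        if not expandable:
            return None
        x = expandable[0]
        if g.out_degree(x) == 0:
            return None
        frontier.remove(x)
        visited.add(x)
        frontier |= set(g.successors(x)) - visited
        if u in frontier:
            return None
    return None


# ---------------------------------------------------------------------------
# popping rules


def _retained_order(branches: list[Branch]) -> list[Branch]:
    """Most coverage first; coverage ties broken by lexicographic sequence."""
    return sorted(branches, key=lambda b: (-b.cov, b.seq))


def pop_simple_bubble(b: Bubble, k: int) -> PoppedRecord | None:
    """Short-bubble rule: pop when branch length < 3k and the branches
    differ by at most two substitutions within k bases of each other."""
    if b.kind != "simple":
        raise ValueError("pop_simple_bubble requires a simple bubble")
    s1, s2 = b.branches[0].seq, b.branches[1].seq
    if max(len(s1), len(s2)) >= 3 * k:
        return None
    if len(s1) != len(s2):
        return None  # substitutions only; length change is not this rule
    diffs = [i for i, (a, c) in enumerate(zip(s1, s2)) if a != c]
    if not 1 <= len(diffs) <= 2:
        return None
    if len(diffs) == 2 and diffs[1] - diffs[0] > k:
        return None  # SNVs separated by more than k form separate bubbles
    ordered = _retained_order(b.branches)
    return PoppedRecord(b.source, b.sink, ordered[0], ordered[1:], "short_two_snv")


def alignment_identity(s1: str, s2: str) -> float:
    """Percent identity of a global alignment: matches / columns x 100.

    Computed on the most compact minimal-edit alignment, whose column
    count is max(len(s1), len(s2)); co-optimal alignments that pad extra
    indel columns would make the ratio path-dependent, so the compact form
    is the definition.  Equal-length branches with m mismatches score
    (L - m) / L; a pure b-base indel scores (L - b) / L.
    """
    d = edlib.align(s1, s2, mode="NW", task="distance")["editDistance"]
    cols = max(len(s1), len(s2))
    return 100.0 * (cols - d) / cols


def pop_long_bubble(b: Bubble, k: int, min_identity: float = 90.0) -> PoppedRecord | None:
    """Long-bubble rule: branches of length >= 3k are popped when their
    global alignment identity is at least min_identity percent."""
    if b.kind != "simple":
        raise ValueError("pop_long_bubble requires a simple bubble")
    s1, s2 = b.branches[0].seq, b.branches[1].seq
    if max(len(s1), len(s2)) < 3 * k:
        return None
    ident = alignment_identity(s1, s2)
    if ident < min_identity:
        return None
    ordered = _retained_order(b.branches)
    return PoppedRecord(b.source, b.sink, ordered[0], ordered[1:], "long_identity", ident)


# ---------------------------------------------------------------------------
# complex bubbles


def longest_interior_path(g: nx.DiGraph, b: Bubble, overlap: int = 0) -> int:
    """Length in bases of the longest u->v path through the interior.

    Each interior vertex contributes len(seq) - overlap bases (overlap is
    the (k-1)-base junction overlap of a contig graph; 0 for plain vertex
    graphs), and a final overlap is subtracted for the junction into the
    sink.  Computed by dynamic programming over a topological order.
    """
    sub = g.subgraph(b.interior)
    if not nx.is_directed_acyclic_graph(sub):
        raise ValueError("complex bubble interior contains a cycle")
    order = list(nx.topological_sort(sub))
    best: dict = {}
    for x in order:
        w = len(g.nodes[x]["seq"]) - overlap
        preds = [p for p in g.predecessors(x) if p in b.interior]
        incoming = max((best[p] for p in preds), default=0)
        if b.source in g.predecessors(x) or preds:
            best[x] = incoming + w
    ends = [best[x] for x in b.interior if b.sink in g.successors(x) and x in best]
    if not ends:
        raise ValueError("no interior path from source to sink")
    return max(ends) - overlap


def resolve_complex_bubble(g: nx.DiGraph, b: Bubble, overlap: int = 0) -> tuple[str, int]:
    """Replace a complex bubble's interior with Ns: returns the spanned
    sequence source + N*L + sink and L (clamped to >= 1 N in the output)."""
    if b.kind != "complex":
        raise ValueError("resolve_complex_bubble requires a complex bubble")
    span = longest_interior_path(g, b, overlap=overlap)
    seq = g.nodes[b.source]["seq"] + "N" * max(span, 1) + g.nodes[b.sink]["seq"]
    return seq, span


# ---------------------------------------------------------------------------
# pipeline application on doubled contig graphs


def _mirror(node):
    cid, o = node
    return (cid, "-" if o == "+" else "+")


def _remove_contig(g: nx.DiGraph, node) -> None:
    for n in (node, _mirror(node)):
        if g.has_node(n):
            g.remove_node(n)


def _weighted_cov(parts: list[tuple[str, float]], k: int) -> float:
    wsum = sum((len(s) - k + 1) * c for s, c in parts)
    w = sum(len(s) - k + 1 for s, c in parts)
    return wsum / w if w else 0.0


def compact_contig_graph(g: nx.DiGraph) -> None:
    """Merge non-branching chains in place, keeping mirror symmetry."""
    from ._kmers import revcomp

    overlap = g.graph.get("overlap", 0)
    k = g.graph.get("k", overlap + 1)
    counter = g.graph.get("merge_counter", 0)

    def unique_next(x):
        succs = list(g.successors(x))
        if len(succs) != 1:
            return None
        y = succs[0]
        if y == x or y == _mirror(x) or g.in_degree(y) != 1:
            return None
        return y

    done: set = set()
    for start in sorted(g.nodes, key=str):
        if start in done or not g.has_node(start):
            continue
        # walk back to the chain head
        head = start
        seen = {head, _mirror(head)}
        while True:
            preds = list(g.predecessors(head))
            if len(preds) != 1 or unique_next(preds[0]) != head or preds[0] in seen:
                break
            head = preds[0]
            seen.add(head)
            seen.add(_mirror(head))
        chain = [head]
        seen = {head, _mirror(head)}
        cur = head
        while True:
            nxt = unique_next(cur)
            if nxt is None or nxt in seen:
                break
            chain.append(nxt)
            seen.add(nxt)
            seen.add(_mirror(nxt))
            cur = nxt
        done.update(seen)
        if len(chain) < 2:
            continue
        parts = [(g.nodes[x]["seq"], g.nodes[x]["cov"]) for x in chain]
        seq = parts[0][0] + "".join(s[overlap:] for s, _ in parts[1:])
        cov = _weighted_cov(parts, k)
        counter += 1
        new = (f"m{counter:06d}", "+")
        tail = chain[-1]
        preds = [p for p in g.predecessors(chain[0]) if p not in chain]
        nexts = [s for s in g.successors(tail) if s not in chain]
        for x in chain:
            _remove_contig(g, x)
        g.add_node(new, seq=seq, cov=cov)
        g.add_node(_mirror(new), seq=revcomp(seq), cov=cov)
        for p in preds:
            if g.has_node(p):
                g.add_edge(p, new)
                g.add_edge(_mirror(new), _mirror(p))
        for s in nexts:
            if g.has_node(s):
                g.add_edge(new, s)
                g.add_edge(_mirror(s), _mirror(new))
    g.graph["merge_counter"] = counter


def process_bubbles(
    g: nx.DiGraph, k: int, max_interior: int = 64, min_identity: float = 90.0
) -> list[PoppedRecord]:
    """Iteratively pop simple bubbles and span complex ones on a doubled
    contig graph, innermost-first with re-scanning, until a fixed point."""
    from ._kmers import revcomp

    overlap = g.graph.get("overlap", k - 1)
    records: list[PoppedRecord] = []
    counter = 0
    while True:
        compact_contig_graph(g)
        bubs = find_bubbles(g, minimal_only=True, max_interior=max_interior)
        bubs.sort(key=lambda b: (len(b.interior), str(b.source), str(b.sink)))
        touched: set = set()
        changed = False
        for b in bubs:
            involved = b.nodes | {_mirror(n) for n in b.nodes}
            if involved & touched:
                continue
            if b.kind == "simple":
                rec = pop_simple_bubble(b, k) or pop_long_bubble(b, k, min_identity)
                if rec is None:
                    continue
                for br in rec.discarded_branches:
                    for n in br.nodes:
                        _remove_contig(g, n)
                records.append(rec)
            else:
                seq, span = resolve_complex_bubble(g, b, overlap=overlap)
                cov = _weighted_cov(
                    [
                        (g.nodes[b.source]["seq"], g.nodes[b.source]["cov"]),
                        (g.nodes[b.sink]["seq"], g.nodes[b.sink]["cov"]),
                    ],
                    k,
                )
                counter += 1
                new = (f"x{counter:06d}", "+")
                preds = [p for p in g.predecessors(b.source) if p not in involved]
                nexts = [s for s in g.successors(b.sink) if s not in involved]
                interior_branches = [
                    Branch((x,), g.nodes[x]["seq"], g.nodes[x]["cov"])
                    for x in sorted(b.interior, key=str)
                ]
                for n in sorted(b.nodes, key=str):
                    _remove_contig(g, n)
                g.add_node(new, seq=seq, cov=cov)
                g.add_node(_mirror(new), seq=revcomp(seq), cov=cov)
                for p in preds:
                    if g.has_node(p):
                        g.add_edge(p, new)
                        g.add_edge(_mirror(new), _mirror(p))
                for s in nexts:
                    if g.has_node(s):
                        g.add_edge(new, s)
                        g.add_edge(_mirror(s), _mirror(new))
                records.append(
                    PoppedRecord(
                        b.source,
                        b.sink,
                        Branch((new,), seq, cov),
                        interior_branches,
                        "complex_span",
                    )
                )
            touched |= involved
            changed = True
        if not changed:
            break
    return records


def contigs_from_graph(g: nx.DiGraph):
    """Final (id, seq, cov) triples, one per contig, '+' orientation,
    sorted by sequence for determinism."""
    out = []
    seen = set()
    for cid, o in g.nodes:
        if cid in seen:
            continue
        seen.add(cid)
        node = (cid, "+") if g.has_node((cid, "+")) else (cid, o)
        out.append((cid, g.nodes[node]["seq"], g.nodes[node]["cov"]))
    out.sort(key=lambda t: t[1])
    return [(f"ctg{i:06d}", seq, cov) for i, (_, seq, cov) in enumerate(out)]
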
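"""Maximum orthogonal edge cover (MAX-OREC) algorithms.

An *orthogonal edge cover* of a genome-colored graph is an edge subset whose
connected components each contain at most one vertex per color; maximizing
the number of covered vertices (MAX-OREC) covers as many genes as possible
by orthology evidence, so that the genes left uncovered become inparalog
candidates.

Three solvers are provided:

``approx_orec``
    The 2/3-approximation.  Per color x, a maximum-cardinality bipartite
    matching M(x) between the color-x vertices and everything else covers
    the largest possible number of color-x vertices.  The union
    R = U_x M(x) is 2-neighborhood-limited (2NL: every vertex has at most
    two neighbors of any one color).  On that union, the edges lying on
    two-color alternating paths are re-matched, the remainder of R is kept,
    and a minimal perfect edge cover of the result is returned.  Each
    odd-length alternating path costs at most one uncovered vertex, which
    yields the covered-count guarantees
    ``covered >= opt - odd_count`` and ``covered > (2/3) * opt``.

``heuristic_orec``
    A simpler, faster-in-practice alternative: union of maximum bipartite
    matchings over every unordered *pair* of colors, followed by a minimal
    perfect edge cover.  Performs better on dense graphs.

``exact_orec_bruteforce``
    An exhaustive oracle for small graphs; used to validate the
    approximation guarantee.

All routines are deterministic: ties are broken by sorted vertex id, and
graphs are traversed in sorted insertion order.
"""

from __future__ import annotations

import itertools
import json
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, TextIO, Union

import networkx as nx

from .graph_io import (
    Edge,
    InputError,
    SimilarityGraph,
    canonical_edge,
    is_orthogonal,
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Matching:
    """A set of pairwise vertex-disjoint edges."""

    edges: frozenset[Edge]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for u, v in self.edges:
            if u in seen or v in seen:
                raise ValueError("matching edges are not vertex-disjoint")
            seen.update((u, v))

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def vertices(self) -> frozenset[str]:
        return frozenset(v for e in self.edges for v in e)


class TwoNLGraph:
    """A colored graph that is 2-neighborhood-limited: every vertex has at
    most two neighbors of any single color.  The union of per-color maximum
    matchings has this property by construction."""

    def __init__(self, colors: Mapping[str, str], edges: Iterable[Edge]) -> None:
        g = nx.Graph()
        g.add_nodes_from(sorted(colors))
        for u, v in sorted(canonical_edge(*e) for e in edges):
            if u == v:
                raise InputError(f"self-loop on vertex {u!r}")
            if u not in colors or v not in colors:
                raise InputError("edge references vertex without a color")
            g.add_edge(u, v)
        self._g = g
        self._colors = dict(colors)

    @property
    def nx_graph(self) -> nx.Graph:
        return self._g

    @property
    def colors(self) -> Mapping[str, str]:
        return self._colors

    @property
    def vertices(self) -> list[str]:
        return sorted(self._g.nodes)

    @property
    def edges(self) -> frozenset[Edge]:
        return frozenset(canonical_edge(u, v) for u, v in self._g.edges)

    def validate(self) -> None:
        """Raise :class:`InputError` if the 2NL property is violated."""
        for v in self._g.nodes:
            per_color: dict[str, int] = defaultdict(int)
            for w in self._g.adj[v]:
                per_color[self._colors[w]] += 1
                if per_color[self._colors[w]] > 2:
                    raise InputError(
                        f"not 2NL: vertex {v!r} has >2 neighbors of color "
                        f"{self._colors[w]!r}"
                    )


@dataclass(frozen=True)
class AlternatingPathSet:
    """Decomposition of a 2NL graph's two-color alternating structures.

    ``paths`` are maximal alternating paths with at least three vertices
    (vertex sequences); ``cycles`` are alternating cycles, which behave like
    even paths (perfectly matchable).  ``edges`` is the union P of all their
    edges.  Path *length* is the number of vertices; ``odd_count`` counts
    the odd-length paths, each of which costs at most one uncovered vertex.
    """

    paths: tuple[tuple[str, ...], ...]
    cycles: tuple[tuple[str, ...], ...]
    edges: frozenset[Edge]
    odd_count: int


@dataclass(frozen=True)
class OrthogonalEdgeCover:
    """An edge subset whose components are color-orthogonal, plus the
    induced covered/uncovered vertex partition."""

    edges: frozenset[Edge]
    covered: frozenset[str]
    uncovered: frozenset[str]
    algorithm: str = ""
    odd_count: Optional[int] = None
    #: vertices untouched by the union of per-color matchings; together with
    #: ``odd_count`` this bounds the uncovered count of the approximation
    n_union_isolated: Optional[int] = None

    @property
    def n_covered(self) -> int:
        return len(self.covered)

    @property
    def n_uncovered(self) -> int:
        return len(self.uncovered)

    def component_sizes(self) -> list[int]:
        g = nx.Graph(list(self.edges))
        return sorted((len(c) for c in nx.connected_components(g)), reverse=True)

    def summary(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "n_edges": len(self.edges),
            "n_covered": self.n_covered,
            "n_uncovered": self.n_uncovered,
            "odd_count": self.odd_count,
            "component_sizes": self.component_sizes(),
        }


def _make_cover(
    edges: Iterable[Edge],
    all_vertices: Iterable[str],
    algorithm: str,
    odd_count: Optional[int] = None,
) -> OrthogonalEdgeCover:
    edges = frozenset(canonical_edge(*e) for e in edges)
    covered = frozenset(v for e in edges for v in e)
    uncovered = frozenset(all_vertices) - covered
    return OrthogonalEdgeCover(edges, covered, uncovered, algorithm, odd_count)


def _assert_orthogonal(cover: OrthogonalEdgeCover, colors: Mapping[str, str]) -> None:
    g = nx.Graph(list(cover.edges))
    for comp in nx.connected_components(g):
        seen = [colors[v] for v in comp]
        if len(set(seen)) != len(seen):
            raise AssertionError(
                f"internal error: {cover.algorithm} produced a non-orthogonal "
                f"component {sorted(comp)}"
            )


# ---------------------------------------------------------------------------
# Bipartite matchings and the union graph
# ---------------------------------------------------------------------------

def _bipartite_max_matching(
    top: Sequence[str], edges: Iterable[Edge]
) -> frozenset[Edge]:
    """Maximum-cardinality matching of a bipartite graph given one side.

    A self-contained Hopcroft-Karp over sorted adjacency lists: the
    matchings are unweighted on purpose (the cover objective counts
    vertices, not weight) and fully deterministic — library routines that
    iterate hash-ordered node sets are not reproducible across processes.
    """
    edges = sorted({canonical_edge(*e) for e in edges})
    if not edges:
        return frozenset()
    top_set = set(top)
    adj: dict[str, list[str]] = defaultdict(list)
    for a, b in edges:
        u, w = (a, b) if a in top_set else (b, a)
        if u not in top_set or w in top_set:
            raise InputError(f"edge ({a!r}, {b!r}) is not bipartite across the split")
        adj[u].append(w)
    left = sorted(adj)
    for u in left:
        adj[u].sort()
    inf = float("inf")
    mate_l: dict[str, Optional[str]] = {u: None for u in left}
    mate_r: dict[str, Optional[str]] = {}
    dist: dict[str, float] = {}

    from collections import deque

    def bfs() -> bool:
        queue: deque[str] = deque()
        for u in left:
            if mate_l[u] is None:
                dist[u] = 0
                queue.append(u)
            else:
                dist[u] = inf
        found = False
        while queue:
            u = queue.popleft()
            for w in adj[u]:
                nxt = mate_r.get(w)
                if nxt is None:
                    found = True
                elif dist[nxt] == inf:
                    dist[nxt] = dist[u] + 1
                    queue.append(nxt)
        return found

    def dfs(u: str) -> bool:
        for w in adj[u]:
            nxt = mate_r.get(w)
            if nxt is None or (dist[nxt] == dist[u] + 1 and dfs(nxt)):
                mate_l[u] = w
                mate_r[w] = u
                return True
        dist[u] = inf
        return False

    import sys

    needed = 4 * len(left) + 1000  # augmenting-path DFS recursion headroom
    if sys.getrecursionlimit() < needed:
        sys.setrecursionlimit(needed)
    while bfs():
        for u in left:
            if mate_l[u] is None:
                dfs(u)
    return frozenset(
        canonical_edge(u, w) for u, w in mate_l.items() if w is not None
    )


def color_bipartite_matching(graph: SimilarityGraph, color: str) -> Matching:
    """Maximum-cardinality matching between the vertices of one genome and
    all other vertices, over inter-species edges only.  Covers the maximum
    possible number of vertices of that genome without breaking
    orthogonality."""
    top = [v for v in graph.vertices if graph.color(v) == color]
    edges = [
        (a, b)
        for a, b, _ in graph.inter_edges
        if graph.color(a) == color or graph.color(b) == color
    ]
    return Matching(_bipartite_max_matching(top, edges))


def build_union_graph(graph: SimilarityGraph) -> TwoNLGraph:
    """Union R of the per-color maximum matchings; 2NL by construction
    (a color-y neighbor of v arises only from M(c(v)) or M(y))."""
    r: set[Edge] = set()
    for color in graph.genomes:
        r |= color_bipartite_matching(graph, color).edges
    h = TwoNLGraph({v: graph.color(v) for v in graph.vertices}, r)
    h.validate()
    return h


# ---------------------------------------------------------------------------
# Alternating paths
# ---------------------------------------------------------------------------

def find_alternating_paths(h: TwoNLGraph) -> AlternatingPathSet:
    """Maximal two-color alternating paths and cycles of a 2NL graph.

    Every edge lies between exactly one unordered pair of colors, and within
    the subgraph spanned by one color pair each vertex has degree <= 2 (the
    2NL bound), so that subgraph decomposes uniquely into simple paths and
    cycles.  Components with a single edge are trivial (two vertices) and
    are not alternating paths of length >= 3; they are excluded from P.
    Runs in time linear in the number of edges.
    """
    h.validate()
    by_pair: dict[tuple[str, str], dict[str, list[str]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for u, v in sorted(h.edges):
        pair = tuple(sorted((h.colors[u], h.colors[v])))
        if pair[0] == pair[1]:
            # same-color edges cannot lie in any orthogonal component and
            # never arise from inter-species matchings; ignore defensively
            continue
        by_pair[pair][u].append(v)
        by_pair[pair][v].append(u)

    paths: list[tuple[str, ...]] = []
    cycles: list[tuple[str, ...]] = []
    p_edges: set[Edge] = set()

    for pair in sorted(by_pair):
        adj = by_pair[pair]
        for vs in adj.values():
            vs.sort()
        visited: set[str] = set()
        # paths first: walk from each degree-1 endpoint
        for start in sorted(v for v in adj if len(adj[v]) == 1):
            if start in visited:
                continue
            seq = [start]
            visited.add(start)
            prev: Optional[str] = None
            cur = start
            while True:
                nxt = [w for w in adj[cur] if w != prev]
                if not nxt or nxt[0] in visited:
                    break
                prev, cur = cur, nxt[0]
                seq.append(cur)
                visited.add(cur)
            if len(seq) >= 3:
                paths.append(tuple(seq))
                p_edges.update(
                    canonical_edge(a, b) for a, b in zip(seq, seq[1:])
                )
        # remaining components are cycles (all degrees exactly 2)
        for start in sorted(adj):
            if start in visited:
                continue
            seq = [start]
            visited.add(start)
            prev, cur = None, start
            while True:
                nxt = [w for w in adj[cur] if w != prev]
                if not nxt:
                    break
                step = nxt[0]
                if step == start:
                    break
                prev, cur = cur, step
                seq.append(cur)
                visited.add(cur)
            cycles.append(tuple(seq))
            ring = seq + [seq[0]]
            p_edges.update(canonical_edge(a, b) for a, b in zip(ring, ring[1:]))

    odd_count = sum(1 for seq in paths if len(seq) % 2 == 1)
    return AlternatingPathSet(
        paths=tuple(sorted(paths)),
        cycles=tuple(sorted(cycles)),
        edges=frozenset(p_edges),
        odd_count=odd_count,
    )


# ---------------------------------------------------------------------------
# Minimal perfect edge cover
# ---------------------------------------------------------------------------

def minimal_perfect_edge_cover(graph: nx.Graph) -> frozenset[Edge]:
    """A minimal perfect edge cover of every component with >= 2 vertices.

    Every non-isolated vertex is touched by at least one returned edge, no
    returned edge can be removed without uncovering a vertex, and every
    component of the returned edge set is a star.  Isolated vertices of the
    input pass through uncovered.

    Built from a deterministic greedy maximal matching: each unmatched
    vertex is then attached to its smallest neighbor (necessarily matched,
    by maximality), and redundant edges — those whose two endpoints are both
    covered elsewhere — are pruned in sorted order.  Minimality does not
    require the underlying matching to be maximum; the covered vertex set
    is the same either way.
    """
    cover: set[Edge] = set()
    mate: dict[str, str] = {}
    for u in sorted(graph.nodes):
        if u in mate:
            continue
        for w in sorted(graph.adj[u]):
            if w not in mate and w != u:
                mate[u] = w
                mate[w] = u
                cover.add(canonical_edge(u, w))
                break
    for u in sorted(graph.nodes):
        if u not in mate and graph.degree[u] > 0:
            # all neighbors are matched, else the greedy pass would have
            # matched u
            cover.add(canonical_edge(u, min(graph.adj[u])))
    # prune: drop any edge both of whose endpoints stay covered without it
    degree: dict[str, int] = defaultdict(int)
    for u, v in cover:
        degree[u] += 1
        degree[v] += 1
    for u, v in sorted(cover):
        if degree[u] > 1 and degree[v] > 1:
            cover.discard((u, v))
            degree[u] -= 1
            degree[v] -= 1
    return frozenset(cover)


# ---------------------------------------------------------------------------
# Approximation algorithm
# ---------------------------------------------------------------------------

def max_orec_2nl(h: TwoNLGraph) -> OrthogonalEdgeCover:
    """Orthogonal edge cover of a 2NL graph with at most ``odd_count``
    uncovered non-isolated vertices.

    Collect the alternating-path edge set P, replace each alternating path
    or cycle by an every-other-edge matching of itself, re-join with
    R \\ P, and return a minimal perfect edge cover of the result.  The
    per-structure matchings cover every vertex of an even path or cycle and
    all but one chosen vertex of an odd path, which yields the odd-path
    bound and, on graphs without odd paths, a perfect cover.

    The per-structure matchings are taken independently rather than as one
    global matching on (v(P), P): paths of different color pairs can share
    a vertex, and no single matching can realize the every-other-edge
    selection of two paths through the same vertex — a shared vertex may
    legitimately keep one edge of each.  The result stays orthogonal: each
    vertex keeps at most one edge per color pair, so no vertex ends up with
    two neighbors of one color (such a pair would itself have been an
    alternating path inside P), and the final star components repeat no
    color.  The exposed vertex of an odd path is chosen, deterministically,
    among the path's even positions, preferring one that stays covered
    anyway — through an R \\ P edge or through another alternating
    structure.
    """
    aps = find_alternating_paths(h)
    r = h.edges
    p = aps.edges

    supported = {v for e in (r - p) for v in e}
    structures = list(aps.paths) + list(aps.cycles)
    membership: dict[str, int] = defaultdict(int)
    for seq in structures:
        for v in seq:
            membership[v] += 1

    kept: set[Edge] = set()
    for seq in aps.paths:
        length = len(seq)
        if length % 2 == 0:
            kept.update(
                canonical_edge(seq[i], seq[i + 1]) for i in range(0, length - 1, 2)
            )
            continue
        # odd path: expose one even-position vertex, preferring one that is
        # covered through R \ P or through another path/cycle
        positions = range(0, length, 2)
        expose = next(
            (
                i
                for i in positions
                if seq[i] in supported or membership[seq[i]] > 1
            ),
            0,
        )
        kept.update(
            canonical_edge(seq[i], seq[i + 1]) for i in range(0, expose - 1, 2)
        )
        kept.update(
            canonical_edge(seq[i], seq[i + 1])
            for i in range(expose + 1, length - 1, 2)
        )
    for seq in aps.cycles:
        kept.update(
            canonical_edge(seq[i], seq[i + 1]) for i in range(0, len(seq) - 1, 2)
        )

    e2 = kept | (r - p)
    h2 = nx.Graph()
    h2.add_nodes_from(h.vertices)
    h2.add_edges_from(sorted(e2))
    cover_edges = minimal_perfect_edge_cover(h2)
    cover = _make_cover(cover_edges, h.vertices, "approx-2nl", aps.odd_count)
    _assert_orthogonal(cover, h.colors)
    return cover


def approx_orec(graph: SimilarityGraph) -> OrthogonalEdgeCover:
    """The 2/3-approximation for MAX-OREC on a similarity graph.

    Covers more than 2/3 of the optimal number of vertices, and at least
    the optimum minus the number of odd alternating paths.  Only
    inter-species edges participate (an intra-species edge can never lie in
    an orthogonal component).
    """
    h = build_union_graph(graph)
    cover = max_orec_2nl(h)
    touched = {v for e in h.edges for v in e}
    cover = OrthogonalEdgeCover(
        cover.edges, cover.covered, cover.uncovered, "approx", cover.odd_count,
        n_union_isolated=len(h.vertices) - len(touched),
    )
    result = is_orthogonal(cover.edges, graph)
    if not result:
        raise AssertionError(
            f"internal error: approx cover not orthogonal at {result.violation}"
        )
    return cover


# ---------------------------------------------------------------------------
# Fast heuristic
# ---------------------------------------------------------------------------

def heuristic_orec(graph: SimilarityGraph) -> OrthogonalEdgeCover:
    """Pairwise-matching heuristic for MAX-OREC.

    For every unordered pair of genomes, take a maximum bipartite matching
    on the edges between them; union all matchings and return a minimal
    perfect edge cover of that union.  Each pairwise matching contributes at
    most one neighbor of each color to any vertex, so the resulting stars
    are orthogonal.  Faster and better-covering than the approximation on
    dense graphs, but with no worst-case guarantee.
    """
    genomes = graph.genomes
    by_pair: dict[tuple[str, str], list[Edge]] = defaultdict(list)
    for a, b, _ in graph.inter_edges:
        pair = tuple(sorted((graph.color(a), graph.color(b))))
        by_pair[pair].append((a, b))
    union: set[Edge] = set()
    for x, y in itertools.combinations(genomes, 2):
        edges = by_pair.get((x, y))
        if not edges:
            continue
        top = sorted({v for e in edges for v in e if graph.color(v) == x})
        union |= _bipartite_max_matching(top, edges)
    h = nx.Graph()
    h.add_nodes_from(graph.vertices)
    h.add_edges_from(sorted(union))
    cover_edges = minimal_perfect_edge_cover(h)
    cover = _make_cover(cover_edges, graph.vertices, "heuristic")
    result = is_orthogonal(cover.edges, graph)
    if not result:
        raise AssertionError(
            f"internal error: heuristic cover not orthogonal at {result.violation}"
        )
    return cover


# ---------------------------------------------------------------------------
# Exact oracle
# ---------------------------------------------------------------------------

def _exact_component(
    nodes: list[str],
    colors: dict[str, str],
    adj: dict[str, set[str]],
) -> tuple[int, list[Edge]]:
    """Exact MAX-OREC on one connected component via bitmask dynamic
    programming over star packings.

    Any orthogonal cover can be rewritten, without changing its covered
    vertex set, as vertex-disjoint stars whose center and leaves all have
    distinct colors (take a maximal matching of each component and attach
    the leftovers).  Conversely any such star packing is orthogonal, so
    maximizing covered vertices over star packings is exact.
    """
    m = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    color_of = [colors[v] for v in nodes]
    nbr_by_color: list[dict[str, list[int]]] = []
    for v in nodes:
        groups: dict[str, list[int]] = defaultdict(list)
        for w in sorted(adj[v]):
            groups[colors[w]].append(index[w])
        nbr_by_color.append(dict(groups))

    size = 1 << m
    best_val = [0] * size
    best_star: list[Optional[tuple[int, tuple[int, ...]]]] = [None] * size

    for mask in range(1, size):
        v = (mask & -mask).bit_length() - 1
        rest = mask ^ (1 << v)
        val = best_val[rest]  # option: leave v uncovered
        star = None
        centers = [v] + [u for u in range(m) if (1 << u) & mask and nodes[u] in adj[nodes[v]]]
        for u in centers:
            classes: list[list[Optional[int]]] = []
            feasible = True
            for col in sorted(nbr_by_color[u]):
                avail = [b for b in nbr_by_color[u][col] if (mask >> b) & 1]
                if u != v and col == color_of[v]:
                    if v not in avail:
                        feasible = False
                        break
                    classes.append([v])  # v must be a leaf of this star
                elif avail:
                    avail.append(None)  # type: ignore[arg-type]
                    classes.append(avail)
            if not feasible or not classes:
                continue
            for combo in itertools.product(*classes):
                leaves = tuple(b for b in combo if b is not None)
                if not leaves:
                    continue
                t = 1 << u
                for b in leaves:
                    t |= 1 << b
                if not (t >> v) & 1:
                    continue
                cand = t.bit_count() + best_val[mask & ~t]
                if cand > val:
                    val = cand
                    star = (u, leaves)
        best_val[mask] = val
        best_star[mask] = star

    # reconstruct the chosen stars
    edges: list[Edge] = []
    mask = size - 1
    while mask:
        star = best_star[mask]
        v = (mask & -mask).bit_length() - 1
        if star is None:
            mask ^= 1 << v
            continue
        u, leaves = star
        for b in leaves:
            edges.append(canonical_edge(nodes[u], nodes[b]))
        t = 1 << u
        for b in leaves:
            t |= 1 << b
        mask &= ~t
    return best_val[size - 1], edges


_MAX_COMPONENT_VERTICES = 22


def exact_orec_bruteforce(
    graph: SimilarityGraph, limit: int = 16
) -> OrthogonalEdgeCover:
    """Exhaustive MAX-OREC for small graphs.

    Maximizes the covered-vertex count over *all* orthogonal edge subsets,
    component by component (exponential in component size).  Intra-species
    edges are excluded up front: they can never lie in an orthogonal
    component.  Raises :class:`InputError` when the graph exceeds ``limit``
    inter-species edges; use :func:`approx_orec` instead for such inputs.
    """
    inter = graph.inter_edges
    if len(inter) > limit:
        raise InputError(
            f"graph has {len(inter)} inter-species edges, above the exact-"
            f"search limit {limit}; use approx_orec or heuristic_orec"
        )
    g = nx.Graph()
    g.add_nodes_from(graph.vertices)
    g.add_edges_from((a, b) for a, b, _ in inter)
    colors = {v: graph.color(v) for v in graph.vertices}

    total = 0
    edges: list[Edge] = []
    for comp in nx.connected_components(g):
        if len(comp) == 1:
            continue
        if len(comp) > _MAX_COMPONENT_VERTICES:
            raise InputError(
                f"connected component with {len(comp)} vertices exceeds the "
                f"exact-search capacity ({_MAX_COMPONENT_VERTICES}); use "
                "approx_orec or heuristic_orec"
            )
        nodes = sorted(comp)
        adj = {v: set(g.adj[v]) for v in nodes}
        val, comp_edges = _exact_component(nodes, colors, adj)
        total += val
        edges.extend(comp_edges)

    cover = _make_cover(edges, graph.vertices, "exact")
    if cover.n_covered != total:
        raise AssertionError("internal error: exact reconstruction mismatch")
    result = is_orthogonal(cover.edges, graph)
    if not result:
        raise AssertionError(
            f"internal error: exact cover not orthogonal at {result.violation}"
        )
    return cover


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_cover_tsv(cover: OrthogonalEdgeCover, handle: TextIO) -> None:
    handle.write("gene_a\tgene_b\n")
    for a, b in sorted(cover.edges):
        handle.write(f"{a}\t{b}\n")


def write_uncovered_tsv(cover: OrthogonalEdgeCover, handle: TextIO) -> None:
    handle.write("gene_id\n")
    for v in sorted(cover.uncovered):
        handle.write(f"{v}\n")


def write_cover_summary(cover: OrthogonalEdgeCover, handle: TextIO) -> None:
    json.dump(cover.summary(), handle, indent=2)
    handle.write("\n")


def read_cover_tsv(
    handle: Union[TextIO, Iterable[str]], graph: SimilarityGraph
) -> OrthogonalEdgeCover:
    """Re-read a cover edge list and derive covered/uncovered from the
    graph's vertex set."""
    edges = []
    for line in handle:
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#") or line.startswith("gene_a"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise InputError(f"malformed cover row: {line!r}")
        if not graph.has_edge(fields[0], fields[1]):
            raise InputError(
                f"cover edge ({fields[0]!r}, {fields[1]!r}) not in graph"
            )
        edges.append(canonical_edge(fields[0], fields[1]))
    return _make_cover(edges, graph.vertices, "file")
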
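"""Orthogonal edge cover algorithms: matchings, alternating paths, the
2/3-approximation, the pairwise heuristic and the exact oracle."""

from __future__ import annotations

import networkx as nx
import pytest

from orthocover import (
    GnpSpec,
    InputError,
    TwoNLGraph,
    approx_orec,
    build_union_graph,
    color_bipartite_matching,
    exact_orec_bruteforce,
    find_alternating_paths,
    gnp_colored_graph,
    heuristic_orec,
    is_orthogonal,
    max_orec_2nl,
    minimal_perfect_edge_cover,
)

from conftest import (
    is_minimal_cover,
    is_perfect_cover,
    is_star_forest,
    make_graph,
    naive_exact_covered,
)


def random_graph(seed: int, n: int = 8, k: int = 3, p: float = 0.4):
    return gnp_colored_graph(GnpSpec(n=n, edge_prob=p, k=k, seed=seed))


# ---------------------------------------------------------------------------
# bipartite matchings and the union graph
# ---------------------------------------------------------------------------

class TestColorBipartiteMatching:
    def test_star_matches_once(self):
        graph = make_graph(
            {"a": "A", "b1": "B", "b2": "B", "b3": "B"},
            [("a", "b1", 90), ("a", "b2", 90), ("a", "b3", 90)],
        )
        assert len(color_bipartite_matching(graph, "A")) == 1

    def test_complete_bipartite_perfect(self):
        graph = make_graph(
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
            [(a, b, 90) for a in ("a1", "a2") for b in ("b1", "b2")],
        )
        assert len(color_bipartite_matching(graph, "A")) == 2

    def test_absent_color_empty(self):
        graph = make_graph({"a": "A", "b": "B"}, [("a", "b", 90)])
        assert len(color_bipartite_matching(graph, "Z")) == 0

    def test_intra_edges_ignored(self):
        graph = make_graph(
            {"a1": "A", "a2": "A"}, [("a1", "a2", 90)]
        )
        assert len(color_bipartite_matching(graph, "A")) == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_networkx_matching_number(self, seed):
        """Cross-check cardinality against networkx Hopcroft-Karp."""
        graph = random_graph(seed)
        for color in graph.genomes:
            top = [v for v in graph.vertices if graph.color(v) == color]
            b = nx.Graph()
            b.add_nodes_from(graph.vertices)
            b.add_edges_from(
                (a, c)
                for a, c, _ in graph.inter_edges
                if graph.color(a) == color or graph.color(c) == color
            )
            expected = len(nx.bipartite.hopcroft_karp_matching(b, top)) // 2
            assert len(color_bipartite_matching(graph, color)) == expected


class TestUnionGraph:
    def test_single_edge_deduplicated(self):
        graph = make_graph({"a": "A", "b": "B"}, [("a", "b", 90)])
        assert build_union_graph(graph).edges == frozenset({("a", "b")})

    @pytest.mark.parametrize("seed", range(10))
    def test_union_is_2nl(self, seed):
        """Every vertex of R has at most two neighbors of any one color."""
        h = build_union_graph(random_graph(seed, n=12, k=4, p=0.5))
        h.validate()  # raises on violation
        for v in h.vertices:
            per_color = {}
            for w in h.nx_graph.adj[v]:
                per_color[h.colors[w]] = per_color.get(h.colors[w], 0) + 1
            assert all(c <= 2 for c in per_color.values())


# ---------------------------------------------------------------------------
# alternating paths
# ---------------------------------------------------------------------------

def _brute_force_p_edges(h: TwoNLGraph) -> frozenset:
    """Independent oracle for P: an edge lies on an alternating path of
    >= 3 vertices iff one endpoint has another neighbor of the other
    endpoint's color."""
    p = set()
    g = h.nx_graph
    for u, v in h.edges:
        ext_u = any(
            w != v and h.colors[w] == h.colors[v] for w in g.adj[u]
        )
        ext_v = any(
            w != u and h.colors[w] == h.colors[u] for w in g.adj[v]
        )
        if ext_u or ext_v:
            p.add((u, v))
    return frozenset(p)


class TestFindAlternatingPaths:
    def test_odd_aba_path(self):
        h = TwoNLGraph(
            {"a1": "A", "b1": "B", "a2": "A"},
            [("a1", "b1"), ("a2", "b1")],
        )
        aps = find_alternating_paths(h)
        assert aps.odd_count == 1
        assert len(aps.paths) == 1 and len(aps.paths[0]) == 3

    def test_three_color_path_has_no_alternating_path(self):
        h = TwoNLGraph(
            {"a": "A", "b": "B", "c": "C"},
            [("a", "b"), ("b", "c")],
        )
        aps = find_alternating_paths(h)
        assert aps.paths == () and aps.edges == frozenset() and aps.odd_count == 0
        assert _brute_force_p_edges(h) == frozenset()

    def test_even_path_not_odd(self):
        h = TwoNLGraph(
            {"a1": "A", "b1": "B", "a2": "A", "b2": "B"},
            [("a1", "b1"), ("a2", "b1"), ("a2", "b2")],
        )
        aps = find_alternating_paths(h)
        assert aps.odd_count == 0 and len(aps.paths) == 1

    def test_alternating_cycle_detected(self):
        h = TwoNLGraph(
            {"a1": "A", "b1": "B", "a2": "A", "b2": "B"},
            [("a1", "b1"), ("b1", "a2"), ("a2", "b2"), ("b2", "a1")],
        )
        aps = find_alternating_paths(h)
        assert aps.paths == () and len(aps.cycles) == 1 and aps.odd_count == 0
        assert len(aps.edges) == 4

    def test_empty_graph(self):
        aps = find_alternating_paths(TwoNLGraph({}, []))
        assert aps.paths == () and aps.odd_count == 0

    def test_non_2nl_input_rejected(self):
        h = TwoNLGraph(
            {"a": "A", "b1": "B", "b2": "B", "b3": "B"},
            [("a", "b1"), ("a", "b2"), ("a", "b3")],
        )
        with pytest.raises(InputError, match="2NL"):
            find_alternating_paths(h)

    @pytest.mark.parametrize("seed", range(10))
    def test_p_matches_brute_force_characterization(self, seed):
        h = build_union_graph(random_graph(seed, n=12, k=4, p=0.5))
        assert find_alternating_paths(h).edges == _brute_force_p_edges(h)


# ---------------------------------------------------------------------------
# minimal perfect edge cover
# ---------------------------------------------------------------------------

class TestMinimalPerfectEdgeCover:
    def test_single_edge(self):
        g = nx.Graph([("a", "b")])
        assert minimal_perfect_edge_cover(g) == frozenset({("a", "b")})

    def test_triangle_two_adjacent_edges(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        cover = minimal_perfect_edge_cover(g)
        assert len(cover) == 2
        assert is_perfect_cover(cover, g) and is_minimal_cover(cover, g)

    def test_four_path_outer_edges(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "d")])
        assert minimal_perfect_edge_cover(g) == frozenset({("a", "b"), ("c", "d")})

    def test_isolated_vertices_pass_through(self):
        g = nx.Graph()
        g.add_nodes_from(["x", "y"])
        g.add_edge("a", "b")
        assert minimal_perfect_edge_cover(g) == frozenset({("a", "b")})

    def test_all_small_connected_graphs(self):
        """Perfect, minimal and star-structured on every connected graph
        with <= 5 vertices (graph atlas)."""
        for g in nx.graph_atlas_g():
            if g.number_of_nodes() < 2 or g.number_of_nodes() > 5:
                continue
            if not nx.is_connected(g):
                continue
            relabeled = nx.relabel_nodes(g, {i: f"v{i}" for i in g.nodes})
            cover = minimal_perfect_edge_cover(relabeled)
            assert is_perfect_cover(cover, relabeled)
            assert is_minimal_cover(cover, relabeled)
            assert is_star_forest(cover)


# ---------------------------------------------------------------------------
# the approximation on 2NL graphs
# ---------------------------------------------------------------------------

class TestMaxOrec2NL:
    def test_odd_path_leaves_one_uncovered(self):
        h = TwoNLGraph(
            {"a1": "A", "b1": "B", "a2": "A"},
            [("a1", "b1"), ("a2", "b1")],
        )
        cover = max_orec_2nl(h)
        assert cover.n_uncovered == 1 and cover.n_covered == 2

    def test_even_path_perfectly_covered(self):
        h = TwoNLGraph(
            {"a1": "A", "b1": "B", "a2": "A", "b2": "B"},
            [("a1", "b1"), ("a2", "b1"), ("a2", "b2")],
        )
        assert max_orec_2nl(h).n_uncovered == 0

    def test_no_odd_paths_implies_perfect_cover(self):
        # star of three colors around one center: no two-color path >= 3
        h = TwoNLGraph(
            {"a": "A", "b": "B", "c": "C", "d": "D"},
            [("a", "b"), ("a", "c"), ("a", "d")],
        )
        assert max_orec_2nl(h).n_uncovered == 0


# ---------------------------------------------------------------------------
# exact oracle
# ---------------------------------------------------------------------------

class TestExactOrec:
    def test_aba_path_optimum_two(self, aba_path):
        assert exact_orec_bruteforce(aba_path).n_covered == 2

    def test_orthogonal_graph_taken_whole(self):
        graph = make_graph(
            {"a": "A", "b": "B", "c": "C"},
            [("a", "b", 90), ("b", "c", 90)],
        )
        assert exact_orec_bruteforce(graph).n_covered == 3

    def test_five_cycle_two_colors_plus_one(self):
        """5-cycle colored (A,B,A,B,C): all five vertices coverable, e.g.
        components {v0,v1} and {v2,v3,v4}; value confirmed by the naive
        subset-enumeration oracle."""
        colors = dict(zip("01234", "ABABC"))
        graph = make_graph(
            {f"v{i}": colors[str(i)] for i in range(5)},
            [(f"v{i}", f"v{(i + 1) % 5}", 90.0) for i in range(5)],
        )
        cover = exact_orec_bruteforce(graph)
        assert cover.n_covered == naive_exact_covered(graph) == 5

    def test_edge_limit_enforced(self):
        graph = random_graph(0, n=10, k=3, p=0.9)
        with pytest.raises(InputError, match="approx_orec"):
            exact_orec_bruteforce(graph, limit=4)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_naive_enumeration(self, seed):
        graph = random_graph(seed, n=6, k=2 + seed % 3, p=0.4)
        if len(graph.edges()) > 12:
            pytest.skip("naive oracle bound")
        assert exact_orec_bruteforce(graph).n_covered == naive_exact_covered(graph)


# ---------------------------------------------------------------------------
# cross-algorithm invariants
# ---------------------------------------------------------------------------

ALGORITHMS = [
    approx_orec,
    heuristic_orec,
    lambda g: exact_orec_bruteforce(g, limit=64),
]


class TestCoverInvariants:
    @pytest.mark.parametrize("seed", range(12))
    def test_outputs_always_orthogonal_and_partition(self, seed):
        graph = random_graph(seed, n=9, k=4, p=0.5)
        for algorithm in ALGORITHMS:
            cover = algorithm(graph)
            assert is_orthogonal(cover.edges, graph)
            assert cover.covered | cover.uncovered == set(graph.vertices)
            assert not (cover.covered & cover.uncovered)

    @pytest.mark.parametrize("seed", range(30))
    def test_approximation_guarantee_and_odd_bound(self, seed):
        """covered(approx) >= max(2/3 * opt (rounded up), opt - odd_count)."""
        k = 2 + seed % 4
        graph = random_graph(seed, n=max(4 + seed % 7, k), k=k, p=0.4)
        exact = exact_orec_bruteforce(graph, limit=64)
        approx = approx_orec(graph)
        assert 3 * approx.n_covered >= 2 * exact.n_covered
        assert approx.n_covered >= exact.n_covered - approx.odd_count
        assert exact.n_covered >= approx.n_covered  # exact is an upper bound

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_bounded_by_union_graph_vertices(self, seed):
        """The union of per-color matchings caps the optimum (no cover can
        beat the per-color maximum matchings)."""
        graph = random_graph(seed, n=8, k=3, p=0.4)
        h = build_union_graph(graph)
        v_r = {v for e in h.edges for v in e}
        assert exact_orec_bruteforce(graph, limit=64).n_covered <= len(v_r)

    @pytest.mark.parametrize("seed", range(8))
    def test_two_genome_equivalence(self, seed):
        """With two genomes both algorithms cover exactly twice the
        bipartite matching number."""
        graph = random_graph(seed, n=10, k=2, p=0.4)
        matching = color_bipartite_matching(graph, graph.genomes[0])
        expected = 2 * len(matching)
        assert approx_orec(graph).n_covered == expected
        assert heuristic_orec(graph).n_covered == expected

    @pytest.mark.parametrize("seed", range(8))
    def test_cover_components_are_stars(self, seed):
        graph = random_graph(seed, n=10, k=4, p=0.5)
        for algorithm in (approx_orec, heuristic_orec):
            assert is_star_forest(algorithm(graph).edges)

    def test_empty_graph_covers(self):
        graph = make_graph({})
        for algorithm in ALGORITHMS:
            cover = algorithm(graph)
            assert cover.edges == frozenset() and cover.n_covered == 0

    def test_determinism(self):
        graph = random_graph(5, n=12, k=4, p=0.5)
        for algorithm in ALGORITHMS:
            assert algorithm(graph).edges == algorithm(graph).edges
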
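"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
from typing import Iterable, Mapping

import pytest

from orthocover import Gene, SimilarityGraph, is_orthogonal


def make_graph(
    colors: Mapping[str, str],
    edges: Iterable[tuple[str, str, float]] = (),
    with_coords: bool = False,
) -> SimilarityGraph:
    """Build a small similarity graph from an id->genome mapping and
    weighted edges; coordinates/lengths are synthesized when requested."""
    genes = []
    for i, (gid, genome) in enumerate(sorted(colors.items())):
        if with_coords:
            start = 1000 + 10_000 * i
            genes.append(
                Gene(gid, genome, chromosome="1", start=start, end=start + 999,
                     length=1000)
            )
        else:
            genes.append(Gene(gid, genome))
    return SimilarityGraph(genes, edges)


def naive_exact_covered(graph: SimilarityGraph, max_edges: int = 14) -> int:
    """Independent MAX-OREC oracle: enumerate every edge subset and keep the
    orthogonal one covering the most vertices.  Exponential in the edge
    count; only for tiny graphs."""
    edges = [(a, b) for a, b, _ in graph.edges()]
    assert len(edges) <= max_edges, "naive oracle limited to tiny graphs"
    best = 0
    for r in range(len(edges) + 1):
        for subset in itertools.combinations(edges, r):
            if is_orthogonal(subset, graph):
                covered = len({v for e in subset for v in e})
                best = max(best, covered)
    return best


def is_perfect_cover(cover: frozenset, graph) -> bool:
    """True iff every non-isolated vertex of ``graph`` (networkx) is touched
    by the cover."""
    touched = {v for e in cover for v in e}
    return all(v in touched for v in graph.nodes if graph.degree[v] > 0)


def is_minimal_cover(cover: frozenset, graph) -> bool:
    """True iff removing any single cover edge uncovers some vertex."""
    for edge in cover:
        remaining = cover - {edge}
        touched = {v for e in remaining for v in e}
        if all(v in touched for v in edge):
            return False
    return True


def is_star_forest(cover: frozenset) -> bool:
    """True iff every component of the edge set is a star (some vertex is
    an endpoint of all its component's edges)."""
    import networkx as nx

    g = nx.Graph(list(cover))
    for comp in nx.connected_components(g):
        comp_edges = [e for e in cover if e[0] in comp]
        if not any(
            all(center in e for e in comp_edges) for center in comp
        ):
            return False
    return True


@pytest.fixture
def aba_path() -> SimilarityGraph:
    """Odd alternating path: two genome-A genes flanking one genome-B gene."""
    return make_graph(
        {"a1": "A", "b1": "B", "a2": "A"},
        [("a1", "b1", 100.0), ("a2", "b1", 100.0)],
    )


@pytest.fixture
def abab_path() -> SimilarityGraph:
    """Even alternating path over two genomes (perfectly coverable)."""
    return make_graph(
        {"a1": "A", "b1": "B", "a2": "A", "b2": "B"},
        [("a1", "b1", 100.0), ("a2", "b1", 100.0), ("a2", "b2", 100.0)],
    )
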
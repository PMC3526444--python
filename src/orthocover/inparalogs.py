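"""Inparalog calling from an orthogonal edge cover.

A gene left uncovered by the edge cover could not be placed in any ortholog
set, so it is taken to have arisen by duplication after the relevant
speciation.  Two calling rules turn uncovered genes into inparalog pairs:

``direct``
    Each uncovered gene is paired with its highest-weight *covered*
    same-genome neighbor (the supporting edge is intra-species, hence
    already above the intra-species threshold).

``chain``
    A chain of duplications, each copy arising from the previous one,
    leaves several uncovered genes of one genome.  Per genome, a
    maximum-weight spanning tree is built over the uncovered genes together
    with their covered same-genome neighbors (the chain's anchor); every
    tree edge touching an uncovered gene becomes a call.  On an isolated
    uncovered gene this reduces to the direct rule.

Which genomes participate is the caller's choice (``restrict_to_species``):
considering more genomes makes the calls robust to gene loss, because a
gene whose ortholog was lost in one genome can still be covered through
another.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, TextIO, Union

import networkx as nx

from .graph_io import (
    Gene,
    InputError,
    SimilarityGraph,
    canonical_edge,
)
from .orec import OrthogonalEdgeCover


@dataclass(frozen=True)
class InparalogCall:
    """A within-genome gene pair flagged as inparalogous.  ``gene_a`` sorts
    before ``gene_b``; ``similarity`` is the weight of the supporting
    intra-species edge."""

    gene_a: str
    gene_b: str
    genome: str
    similarity: float
    rule: str  # "direct" or "chain"

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValueError("gene_a must sort before gene_b")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.gene_a, self.gene_b))


def _call(a: str, b: str, genome: str, similarity: float, rule: str) -> InparalogCall:
    a, b = canonical_edge(a, b)
    return InparalogCall(a, b, genome, similarity, rule)


def detect_inparalogs_direct(
    graph: SimilarityGraph, cover: OrthogonalEdgeCover
) -> list[InparalogCall]:
    """Pair each uncovered gene with its highest-weight covered same-genome
    neighbor.  Ties break toward the lexicographically smallest partner id;
    uncovered genes with no covered intra-species neighbor yield no call.
    """
    calls = []
    for u in sorted(cover.uncovered):
        best: Optional[tuple[float, str]] = None
        for v in graph.neighbors(u, kind="intra"):
            if v not in cover.covered:
                continue
            w = graph.weight(u, v)
            if best is None or w > best[0] or (w == best[0] and v < best[1]):
                best = (w, v)
        if best is not None:
            calls.append(_call(u, best[1], graph.color(u), best[0], "direct"))
    return calls


def _maximum_spanning_tree(
    nodes: Iterable[str], edges: list[tuple[str, str, float]]
) -> list[tuple[str, str, float]]:
    """Kruskal with deterministic tie-breaks: weight descending, then
    lexicographic edge."""
    parent = {v: v for v in nodes}

    def find(v: str) -> str:
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    tree = []
    for a, b, w in sorted(edges, key=lambda e: (-e[2], e[0], e[1])):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            tree.append((a, b, w))
    return tree


def detect_inparalogs_chains(
    graph: SimilarityGraph, cover: OrthogonalEdgeCover
) -> list[InparalogCall]:
    """Chain rule: per genome, a maximum-weight spanning tree over the
    uncovered genes and their covered same-genome neighbors; every tree edge
    incident to at least one uncovered gene becomes a call.  An uncovered
    gene may appear in several calls (tree degree > 1)."""
    uncovered_by_genome: dict[str, set[str]] = defaultdict(set)
    for u in cover.uncovered:
        uncovered_by_genome[graph.color(u)].add(u)

    calls = []
    for genome in sorted(uncovered_by_genome):
        unc = uncovered_by_genome[genome]
        nodes = set(unc)
        for u in unc:
            for v in graph.neighbors(u, kind="intra"):
                if v in cover.covered:
                    nodes.add(v)
        sub_edges = [
            (a, b, w)
            for a, b, w in graph.intra_edges
            if a in nodes and b in nodes
        ]
        sub = nx.Graph()
        sub.add_nodes_from(sorted(nodes))
        sub.add_edges_from((a, b) for a, b, _ in sub_edges)
        for comp in nx.connected_components(sub):
            if not comp & unc:
                continue
            comp_edges = [e for e in sub_edges if e[0] in comp]
            for a, b, w in _maximum_spanning_tree(sorted(comp), comp_edges):
                if a in unc or b in unc:
                    calls.append(_call(a, b, genome, w, "chain"))
    return sorted(calls, key=lambda c: (c.genome, c.gene_a, c.gene_b))


def detect_inparalogs(
    graph: SimilarityGraph,
    cover: OrthogonalEdgeCover,
    rule: str = "chain",
) -> list[InparalogCall]:
    """Dispatch to the selected calling rule."""
    if rule == "direct":
        return detect_inparalogs_direct(graph, cover)
    if rule == "chain":
        return detect_inparalogs_chains(graph, cover)
    raise InputError(f"unknown inparalog rule {rule!r}; expected direct or chain")


def restrict_to_species(
    graph: SimilarityGraph, keep: Iterable[str]
) -> SimilarityGraph:
    """Induced subgraph on a chosen genome set.

    Restricting the genome set moves the speciation relative to which
    inparalogy is defined: a duplication is an inparalogy for the species
    set S iff it postdates the most recent speciation among S.
    """
    keep = set(keep)
    if not keep:
        raise InputError("keep must be a non-empty set of genome labels")
    return graph.restrict(keep)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_calls_tsv(
    calls: Iterable[InparalogCall],
    genes: Mapping[str, Gene],
    handle: TextIO,
) -> None:
    from .dupmodes import UNKNOWN, UNLINKED, physical_distance

    handle.write(
        "gene_a\tgene_b\tgenome\tsimilarity\trule\t"
        "chromosome_a\tchromosome_b\tdistance_bp\n"
    )
    for call in calls:
        a, b = genes[call.gene_a], genes[call.gene_b]
        dist = physical_distance(a, b)
        dist_str = "NA" if dist in (UNKNOWN, UNLINKED) else str(dist)
        if dist == UNLINKED:
            dist_str = "unlinked"
        handle.write(
            f"{call.gene_a}\t{call.gene_b}\t{call.genome}\t"
            f"{call.similarity:g}\t{call.rule}\t"
            f"{a.chromosome or 'NA'}\t{b.chromosome or 'NA'}\t{dist_str}\n"
        )


def read_calls_tsv(
    handle: Union[TextIO, Iterable[str]]
) -> list[InparalogCall]:
    calls = []
    for line in handle:
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#") or line.startswith("gene_a"):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise InputError(f"malformed calls row: {line!r}")
        calls.append(
            _call(fields[0], fields[1], fields[2], float(fields[3]), fields[4])
        )
    return calls
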
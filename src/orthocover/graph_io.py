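"""Genome-colored gene-similarity graphs: parsing, filtering, construction, I/O.

The central object is the :class:`SimilarityGraph`: an undirected weighted
graph whose vertices are genes, colored by the genome they belong to.  Edge
weights are percent similarities in [0, 100] taken from an all-vs-all
homology search (BLAST-tabular-like input).  Edges between genes of
different genomes ("inter-species" edges) are the evidence for orthology on
which the edge-cover algorithms operate; edges within one genome
("intra-species" edges) support inparalog calls downstream.

Two filters are applied at construction time:

* a similarity threshold, separate for inter-species (default 80%) and
  intra-species (default 70%) edges, and
* a length-ratio filter discarding pairs where one gene is more than 1.25
  times longer than the other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional, TextIO, Union

import networkx as nx

MISSING = "."

Edge = tuple[str, str]


class InputError(ValueError):
    """Malformed or inconsistent input data."""


class ConfigError(ValueError):
    """Invalid configuration value."""


def canonical_edge(u: str, v: str) -> Edge:
    """Undirected edge as an ordered pair (lexicographically sorted)."""
    return (u, v) if u <= v else (v, u)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Gene:
    """A gene: a graph vertex carrying its genome (the vertex color) and
    optional chromosomal coordinates.

    Coordinates are 1-based inclusive; strand is never used.  ``length`` may
    be given explicitly (e.g. protein length from the homology search) or be
    derived from the coordinates as ``end - start + 1``.
    """

    id: str
    genome: str
    chromosome: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    length: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("gene id must be a non-empty string")
        if not self.genome:
            raise InputError(f"gene {self.id!r}: genome label must be non-empty")
        if self.start is not None and self.start < 0:
            raise InputError(f"gene {self.id!r}: negative start coordinate")
        if (
            self.chromosome is not None
            and self.start is not None
            and self.end is not None
            and self.end < self.start
        ):
            raise InputError(f"gene {self.id!r}: end < start")

    @property
    def span_length(self) -> Optional[int]:
        """Gene length in bp: the explicit ``length`` if present, otherwise
        ``end - start + 1``, otherwise ``None``."""
        if self.length is not None:
            return self.length
        if self.start is not None and self.end is not None:
            return self.end - self.start + 1
        return None


@dataclass(frozen=True)
class SimilarityRecord:
    """One row of an all-vs-all similarity table: a gene pair and its
    percent similarity."""

    gene_a: str
    gene_b: str
    similarity: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise InputError(f"self-hit record for gene {self.gene_a!r}")
        if not math.isfinite(self.similarity) or not (0.0 <= self.similarity <= 100.0):
            raise InputError(
                f"similarity {self.similarity!r} outside [0, 100] "
                f"for pair ({self.gene_a!r}, {self.gene_b!r})"
            )


@dataclass(frozen=True)
class GraphConfig:
    """Filtering configuration for graph construction.

    ``inclusive_thresholds`` keeps an edge when its weight *equals* the
    threshold; ``merge`` selects how reciprocal/duplicate records for the
    same unordered pair are collapsed (asymmetric alignment can report
    different scores in the two directions).
    """

    interspecies_threshold: float = 80.0
    intraspecies_threshold: float = 70.0
    max_length_ratio: Optional[float] = 1.25
    inclusive_thresholds: bool = True
    merge: str = "max"  # one of max / min / mean

    def __post_init__(self) -> None:
        for name in ("interspecies_threshold", "intraspecies_threshold"):
            value = getattr(self, name)
            if not (0.0 <= value <= 100.0):
                raise ConfigError(f"{name} must lie in [0, 100], got {value}")
        if self.max_length_ratio is not None and self.max_length_ratio <= 1.0:
            raise ConfigError(
                f"max_length_ratio must exceed 1, got {self.max_length_ratio}"
            )
        if self.merge not in ("max", "min", "mean"):
            raise ConfigError(f"merge must be max/min/mean, got {self.merge!r}")


@dataclass(frozen=True)
class TableDialect:
    """Column mapping for a tab-separated similarity table.

    Defaults match BLAST tabular output (outfmt 6): query id, subject id
    and percent identity in columns 0, 1 and 2.
    """

    gene_a_col: int = 0
    gene_b_col: int = 1
    similarity_col: int = 2
    comment_prefix: str = "#"

    @property
    def min_columns(self) -> int:
        return max(self.gene_a_col, self.gene_b_col, self.similarity_col) + 1


BLAST_TABULAR = TableDialect()


class SimilarityGraph:
    """Undirected weighted graph over genes, colored by genome.

    Wraps a :class:`networkx.Graph` whose nodes are gene ids with a ``gene``
    attribute and whose edges carry ``weight`` (percent similarity) and
    ``kind`` (``"inter"`` or ``"intra"``).  Node and edge insertion order is
    sorted so that all downstream algorithms are deterministic.
    """

    def __init__(
        self,
        genes: Union[Mapping[str, Gene], Iterable[Gene]],
        edges: Iterable[tuple[str, str, float]] = (),
    ) -> None:
        if isinstance(genes, Mapping):
            gene_map = dict(genes)
        else:
            gene_map = {}
            for gene in genes:
                if gene.id in gene_map:
                    raise InputError(f"duplicate gene id {gene.id!r}")
                gene_map[gene.id] = gene
        g = nx.Graph()
        for gid in sorted(gene_map):
            g.add_node(gid, gene=gene_map[gid])
        for a, b, w in sorted(canonical_edge(u, v) + (float(w),) for u, v, w in edges):
            if a == b:
                raise InputError(f"self-loop on gene {a!r}")
            for gid in (a, b):
                if gid not in gene_map:
                    raise InputError(f"edge references unknown gene id {gid!r}")
            kind = "intra" if gene_map[a].genome == gene_map[b].genome else "inter"
            g.add_edge(a, b, weight=w, kind=kind)
        self._g = g
        self._genes = gene_map

    # -- basic accessors ----------------------------------------------------

    @property
    def nx_graph(self) -> nx.Graph:
        return self._g

    @property
    def genes(self) -> Mapping[str, Gene]:
        return self._genes

    @property
    def vertices(self) -> list[str]:
        return sorted(self._g.nodes)

    @property
    def genomes(self) -> list[str]:
        return sorted({gene.genome for gene in self._genes.values()})

    def color(self, gid: str) -> str:
        return self._genes[gid].genome

    def weight(self, u: str, v: str) -> float:
        return self._g.edges[u, v]["weight"]

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def edges(self, kind: Optional[str] = None) -> list[tuple[str, str, float]]:
        """Sorted (a, b, weight) triples, optionally restricted to one kind."""
        out = []
        for u, v, data in self._g.edges(data=True):
            if kind is None or data["kind"] == kind:
                a, b = canonical_edge(u, v)
                out.append((a, b, data["weight"]))
        return sorted(out)

    @property
    def inter_edges(self) -> list[tuple[str, str, float]]:
        return self.edges("inter")

    @property
    def intra_edges(self) -> list[tuple[str, str, float]]:
        return self.edges("intra")

    @property
    def n_vertices(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def neighbors(self, gid: str, kind: Optional[str] = None) -> list[str]:
        if kind is None:
            return sorted(self._g.adj[gid])
        return sorted(
            v for v in self._g.adj[gid] if self._g.edges[gid, v]["kind"] == kind
        )

    def inter_subgraph(self) -> nx.Graph:
        """A networkx view-copy containing all vertices but only
        inter-species edges (the orthology evidence)."""
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        for a, b, w in self.inter_edges:
            g.add_edge(a, b, weight=w)
        return g

    def restrict(self, keep: Iterable[str]) -> "SimilarityGraph":
        """Induced subgraph on the genomes in ``keep``."""
        keep = set(keep)
        unknown = keep - set(self.genomes)
        if unknown:
            raise InputError(f"unknown genome label(s): {sorted(unknown)}")
        genes = {gid: g for gid, g in self._genes.items() if g.genome in keep}
        edges = [
            (a, b, w)
            for a, b, w in self.edges()
            if a in genes and b in genes
        ]
        return SimilarityGraph(genes, edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimilarityGraph):
            return NotImplemented
        return self._genes == other._genes and self.edges() == other.edges()

    def __repr__(self) -> str:
        return (
            f"SimilarityGraph({self.n_vertices} genes, "
            f"{len(self.inter_edges)} inter + {len(self.intra_edges)} intra edges, "
            f"{len(self.genomes)} genomes)"
        )


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _lines(stream: Union[TextIO, Iterable[str]]) -> Iterator[str]:
    for line in stream:
        yield line.rstrip("\n").rstrip("\r")


def parse_similarity_table(
    stream: Union[TextIO, Iterable[str]],
    dialect: TableDialect = BLAST_TABULAR,
    on_error: str = "raise",
) -> list[SimilarityRecord]:
    """Parse a tab-separated similarity table into records.

    Comment lines (``dialect.comment_prefix``) and blank lines are skipped.
    A non-numeric similarity field on the *first* data row is taken to be a
    header and skipped.  Self-hits (identical ids in both gene columns) are
    silently dropped.  Other malformed rows either raise :class:`InputError`
    with the 1-based line number (``on_error="raise"``, the default) or are
    skipped (``on_error="skip"``).
    """
    if on_error not in ("raise", "skip"):
        raise ConfigError(f"on_error must be 'raise' or 'skip', got {on_error!r}")
    records: list[SimilarityRecord] = []
    seen_data_row = False
    for lineno, line in enumerate(_lines(stream), start=1):
        if not line.strip() or line.startswith(dialect.comment_prefix):
            continue
        fields = line.split("\t")
        if len(fields) == 1:  # tolerate space/comma separated toy inputs
            fields = [f for f in line.replace(",", " ").split() if f]
        try:
            if len(fields) < dialect.min_columns:
                raise InputError(
                    f"line {lineno}: expected at least {dialect.min_columns} "
                    f"columns, found {len(fields)}"
                )
            raw = fields[dialect.similarity_col]
            try:
                similarity = float(raw)
            except ValueError:
                if not seen_data_row:
                    continue  # header row
                raise InputError(
                    f"line {lineno}: non-numeric similarity {raw!r}"
                ) from None
            a = fields[dialect.gene_a_col]
            b = fields[dialect.gene_b_col]
            if a == b:
                seen_data_row = True
                continue
            try:
                record = SimilarityRecord(a, b, similarity)
            except InputError as exc:
                raise InputError(f"line {lineno}: {exc}") from None
        except InputError:
            if on_error == "skip":
                continue
            raise
        seen_data_row = True
        records.append(record)
    return records


_GENE_COLUMNS = ("id", "genome", "chromosome", "start", "end", "length")


def parse_gene_table(stream: Union[TextIO, Iterable[str]]) -> dict[str, Gene]:
    """Parse a gene metadata TSV with header columns
    ``id genome chromosome start end length``.

    ``chromosome``, ``start``, ``end`` and ``length`` may be ``"."`` for
    unknown.  Returns an id -> :class:`Gene` mapping.
    """
    genes: dict[str, Gene] = {}
    header: Optional[dict[str, int]] = None
    for lineno, line in enumerate(_lines(stream), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = {name.strip().lower(): i for i, name in enumerate(fields)}
            missing = [c for c in ("id", "genome") if c not in header]
            if missing:
                raise InputError(
                    f"line {lineno}: gene table header lacks column(s) {missing}"
                )
            continue

        def get(col: str) -> Optional[str]:
            idx = header.get(col)
            if idx is None or idx >= len(fields):
                return None
            value = fields[idx].strip()
            return None if value in ("", MISSING) else value

        def get_int(col: str) -> Optional[int]:
            value = get(col)
            if value is None:
                return None
            try:
                return int(value)
            except ValueError:
                raise InputError(
                    f"line {lineno}: non-integer {col} value {value!r}"
                ) from None

        gid = get("id")
        genome = get("genome")
        if gid is None or genome is None:
            raise InputError(f"line {lineno}: missing gene id or genome")
        if gid in genes:
            raise InputError(f"line {lineno}: duplicate gene id {gid!r}")
        try:
            genes[gid] = Gene(
                id=gid,
                genome=genome,
                chromosome=get("chromosome"),
                start=get_int("start"),
                end=get_int("end"),
                length=get_int("length"),
            )
        except InputError as exc:
            raise InputError(f"line {lineno}: {exc}") from None
    if header is None:
        raise InputError("gene table is empty (header row required)")
    return genes


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

def build_similarity_graph(
    records: Iterable[SimilarityRecord],
    genes: Union[Mapping[str, Gene], Iterable[Gene]],
    config: GraphConfig = GraphConfig(),
) -> SimilarityGraph:
    """Build the filtered similarity graph from parsed records.

    Reciprocal/duplicate records of one unordered pair are first merged
    (``config.merge``, default: maximum similarity).  The merged edge is
    retained iff

    * the length ratio ``max(len_a, len_b) / min(len_a, len_b)`` does not
      exceed ``config.max_length_ratio`` (skipped if that is ``None``), and
    * the similarity passes the inter- or intra-species threshold, depending
      on whether the genomes differ.
    """
    if not isinstance(genes, Mapping):
        genes = {g.id: g for g in genes}
    merged: dict[Edge, list[float]] = {}
    for rec in records:
        for gid in (rec.gene_a, rec.gene_b):
            if gid not in genes:
                raise InputError(f"similarity record references unknown gene {gid!r}")
        merged.setdefault(canonical_edge(rec.gene_a, rec.gene_b), []).append(
            rec.similarity
        )

    def combine(ws: list[float]) -> float:
        if config.merge == "max":
            return max(ws)
        if config.merge == "min":
            return min(ws)
        return sum(ws) / len(ws)

    edges = []
    for (a, b), weights in merged.items():
        w = combine(weights)
        if config.max_length_ratio is not None:
            la, lb = genes[a].span_length, genes[b].span_length
            for gid, length in ((a, la), (b, lb)):
                if length is None or length <= 0:
                    raise InputError(
                        f"gene {gid!r} has no positive length but the "
                        "length-ratio filter is active"
                    )
            if max(la, lb) / min(la, lb) > config.max_length_ratio:
                continue
        intra = genes[a].genome == genes[b].genome
        threshold = (
            config.intraspecies_threshold if intra else config.interspecies_threshold
        )
        passes = w >= threshold if config.inclusive_thresholds else w > threshold
        if passes:
            edges.append((a, b, w))
    return SimilarityGraph(genes, edges)


# ---------------------------------------------------------------------------
# Components and orthogonality
# ---------------------------------------------------------------------------

def connected_components(
    graph: SimilarityGraph,
    edges: Optional[Iterable[Edge]] = None,
) -> tuple[list[frozenset[str]], frozenset[str]]:
    """Connected components over the given edge subset (default: all edges).

    Returns ``(components, isolated)``: components of size >= 2 (sorted by
    smallest member) and the set of vertices touched by no edge.
    """
    g = nx.Graph()
    g.add_nodes_from(graph.vertices)
    if edges is None:
        g.add_edges_from((u, v) for u, v, _ in graph.edges())
    else:
        for u, v in edges:
            if not graph.has_edge(u, v):
                raise InputError(f"edge ({u!r}, {v!r}) not present in graph")
            g.add_edge(u, v)
    comps = []
    isolated = set()
    for comp in nx.connected_components(g):
        if len(comp) == 1:
            isolated.update(comp)
        else:
            comps.append(frozenset(comp))
    comps.sort(key=min)
    return comps, frozenset(isolated)


@dataclass(frozen=True)
class OrthogonalityResult:
    """Outcome of an orthogonality check; truthy iff orthogonal.  On
    failure, ``violation`` holds the first component with a repeated
    genome color."""

    ok: bool
    violation: Optional[frozenset[str]] = None

    def __bool__(self) -> bool:
        return self.ok


def is_orthogonal(
    edges: Iterable[Edge],
    graph: SimilarityGraph,
) -> OrthogonalityResult:
    """True iff every connected component of the edge subset contains at
    most one vertex per genome color."""
    comps, _ = connected_components(graph, edges)
    for comp in comps:
        colors = [graph.color(v) for v in comp]
        if len(set(colors)) != len(colors):
            return OrthogonalityResult(False, comp)
    return OrthogonalityResult(True)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_gene_table(genes: Mapping[str, Gene], handle: TextIO) -> None:
    handle.write("\t".join(_GENE_COLUMNS) + "\n")
    for gid in sorted(genes):
        g = genes[gid]
        row = [
            g.id,
            g.genome,
            g.chromosome if g.chromosome is not None else MISSING,
            str(g.start) if g.start is not None else MISSING,
            str(g.end) if g.end is not None else MISSING,
            str(g.length) if g.length is not None else MISSING,
        ]
        handle.write("\t".join(row) + "\n")


def write_edge_table(graph: SimilarityGraph, handle: TextIO) -> None:
    """Serialize the graph as a TSV edge list: gene_a, gene_b, weight, kind."""
    handle.write("gene_a\tgene_b\tweight\tkind\n")
    for a, b, w in graph.edges():
        kind = graph.nx_graph.edges[a, b]["kind"]
        handle.write(f"{a}\t{b}\t{w!r}\t{kind}\n")


def read_edge_table(
    handle: Union[TextIO, Iterable[str]],
    genes: Mapping[str, Gene],
) -> SimilarityGraph:
    """Re-read a graph serialized by :func:`write_edge_table`."""
    edges = []
    for lineno, line in enumerate(_lines(handle), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "gene_a":
            continue
        if len(fields) < 3:
            raise InputError(f"line {lineno}: expected >= 3 columns")
        try:
            w = float(fields[2])
        except ValueError:
            raise InputError(
                f"line {lineno}: non-numeric weight {fields[2]!r}"
            ) from None
        edges.append((fields[0], fields[1], w))
    return SimilarityGraph(genes, edges)


def write_graphml(graph: SimilarityGraph, path: str) -> None:
    """Export for visualization: nodes carry genome/chromosome attributes."""
    g = nx.Graph()
    for gid in graph.vertices:
        gene = graph.genes[gid]
        g.add_node(gid, genome=gene.genome, chromosome=gene.chromosome or MISSING)
    for a, b, w in graph.edges():
        g.add_edge(a, b, weight=w, kind=graph.nx_graph.edges[a, b]["kind"])
    nx.write_graphml(g, path)
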
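"""Synthetic inputs: colored G(n, p) random graphs, gene-history scenario
graphs, and the approximation-vs-heuristic benchmark.

The G(n, p) (Gilbert) model places an edge independently with probability
``p`` on each of the n(n-1)/2 vertex pairs; ``p`` is the expected
*completeness* of the graph.  Vertices are colored (assigned to genomes)
round-robin, so the k genomes are balanced.  Edge weights are a constant:
the cover algorithms are unweighted, and the random graphs exercise only
the covering step.

The history scenarios encode small duplication/speciation/loss gene
histories over human, chimp, mouse and rat, together with the ground-truth
inparalog calls they imply, and are used as end-to-end fixtures:

``fig1_full``
    Gene 1 in all four genomes; a duplication on the rodent branch (before
    the mouse/rat split) adds gene 2 to mouse and rat.  With all four
    genomes considered there are no inparalogs: the duplication predates
    the lowest speciation (mouse/rat).

``fig1_no_rat``
    The same history with rat dropped from consideration.  Now the lowest
    speciation for {human, chimp, mouse} predates the duplication, so the
    two mouse copies form one inparalog pair.

``fig3_loss``
    Genes 1 and 2 (duplicated before the primate/rodent split) in human,
    chimp and mouse; gene 1 was lost in rat.  With all four genomes there
    are no inparalogs, but an analysis restricted to {mouse, rat} cannot
    see the loss and infers a false inparalog pair between the two mouse
    genes — the failure mode that multi-genome covering avoids.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .graph_io import ConfigError, Gene, InputError, SimilarityGraph
from .orec import approx_orec, heuristic_orec

_SEED_MOD = 2**31


@dataclass(frozen=True)
class GnpSpec:
    """Parameters of one colored G(n, p) draw."""

    n: int
    edge_prob: float
    k: int
    seed: int = 0
    color_mode: str = "round_robin"  # or "random"

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ConfigError(f"n must be >= 0, got {self.n}")
        if not (0.0 <= self.edge_prob <= 1.0):
            raise ConfigError(f"edge_prob must lie in [0, 1], got {self.edge_prob}")
        if self.n > 0 and not (1 <= self.k <= self.n):
            raise ConfigError(f"k must lie in [1, n], got k={self.k}, n={self.n}")
        if self.color_mode not in ("round_robin", "random"):
            raise ConfigError(f"unknown color_mode {self.color_mode!r}")


def gnp_colored_graph(spec: GnpSpec) -> SimilarityGraph:
    """Draw one colored Gilbert random graph, reproducibly from its seed.

    Same-color pairs that receive an edge become intra-species edges (kept
    in the graph but invisible to the cover algorithms); different-color
    pairs become inter-species edges.  All weights are 100.
    """
    rng = np.random.default_rng(spec.seed)
    width = max(4, len(str(max(spec.n - 1, 0))))
    if spec.color_mode == "round_robin":
        assignment = [i % spec.k for i in range(spec.n)]
    else:
        assignment = list(rng.integers(0, spec.k, size=spec.n))
    genes = [
        Gene(id=f"g{i:0{width}d}", genome=f"G{assignment[i]}")
        for i in range(spec.n)
    ]
    edges = []
    if spec.n >= 2 and spec.edge_prob > 0:
        iu, ju = np.triu_indices(spec.n, k=1)
        mask = rng.random(iu.shape[0]) < spec.edge_prob
        for i, j in zip(iu[mask], ju[mask]):
            edges.append((genes[i].id, genes[j].id, 100.0))
    return SimilarityGraph(genes, edges)


# ---------------------------------------------------------------------------
# History scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioWeights:
    """Percent similarities used when emitting scenario graphs; orthologs
    are slightly more similar than cross-copy or within-genome paralog
    pairs, and everything sits above the default thresholds (80 inter,
    70 intra)."""

    ortholog: float = 96.0
    cross_copy: float = 85.0
    paralog: float = 88.0


@dataclass(frozen=True)
class ScenarioResult:
    """A scenario graph plus its ground truth: the expected inparalog calls
    for the full genome set and, where instructive, for restricted genome
    sets (keyed by frozenset of genome labels)."""

    name: str
    graph: SimilarityGraph
    expected_calls: frozenset[tuple[str, frozenset[str]]]
    restricted_expected: Mapping[frozenset[str], frozenset[tuple[str, frozenset[str]]]]


def _scenario_gene(gid: str, genome: str, chrom: str, start: int) -> Gene:
    return Gene(
        id=gid, genome=genome, chromosome=chrom,
        start=start, end=start + 1999, length=2000,
    )


def _pair(genome: str, a: str, b: str) -> tuple[str, frozenset[str]]:
    return (genome, frozenset((a, b)))


def history_scenario_graph(
    scenario: str, weights: ScenarioWeights = ScenarioWeights()
) -> ScenarioResult:
    """Emit the similarity graph implied by a named gene history, with the
    ground-truth inparalog calls for testing."""
    w = weights
    if scenario == "fig1_full":
        genes = [
            _scenario_gene("human_1", "human", "1", 100_000),
            _scenario_gene("chimp_1", "chimp", "1", 100_000),
            _scenario_gene("mouse_1", "mouse", "5", 100_000),
            _scenario_gene("mouse_2", "mouse", "5", 130_000),
            _scenario_gene("rat_1", "rat", "5", 100_000),
            _scenario_gene("rat_2", "rat", "5", 130_000),
        ]
        copy1 = ["chimp_1", "human_1", "mouse_1", "rat_1"]
        edges = [
            (a, b, w.ortholog)
            for i, a in enumerate(copy1)
            for b in copy1[i + 1:]
        ]
        edges.append(("mouse_2", "rat_2", w.ortholog))
        # cross-copy similarity survives only within the rodents; the copies
        # diverged too far from the primate genes to pass the threshold
        edges.append(("mouse_1", "rat_2", w.cross_copy))
        edges.append(("mouse_2", "rat_1", w.cross_copy))
        edges.append(("mouse_1", "mouse_2", w.paralog))
        edges.append(("rat_1", "rat_2", w.paralog))
        return ScenarioResult(
            scenario, SimilarityGraph(genes, edges),
            expected_calls=frozenset(),
            restricted_expected={
                frozenset(("human", "chimp", "mouse")): frozenset(
                    {_pair("mouse", "mouse_1", "mouse_2")}
                ),
            },
        )
    if scenario == "fig1_no_rat":
        full = history_scenario_graph("fig1_full", weights)
        return ScenarioResult(
            scenario,
            full.graph.restrict({"human", "chimp", "mouse"}),
            expected_calls=frozenset({_pair("mouse", "mouse_1", "mouse_2")}),
            restricted_expected={},
        )
    if scenario == "fig3_loss":
        genes = [
            _scenario_gene("human_1", "human", "5", 200_000),
            _scenario_gene("human_2", "human", "5", 240_000),
            _scenario_gene("chimp_1", "chimp", "5", 200_000),
            _scenario_gene("chimp_2", "chimp", "5", 240_000),
            _scenario_gene("mouse_1", "mouse", "18", 200_000),
            _scenario_gene("mouse_2", "mouse", "18", 240_000),
            _scenario_gene("rat_2", "rat", "18", 240_000),
        ]
        copy1 = ["chimp_1", "human_1", "mouse_1"]
        copy2 = ["chimp_2", "human_2", "mouse_2", "rat_2"]
        edges = [
            (a, b, w.ortholog) for i, a in enumerate(copy1) for b in copy1[i + 1:]
        ]
        edges += [
            (a, b, w.ortholog) for i, a in enumerate(copy2) for b in copy2[i + 1:]
        ]
        edges += [
            (a, b, w.cross_copy)
            for a in copy1
            for b in copy2
            if a.split("_")[0] != b.split("_")[0]
        ]
        edges += [
            ("human_1", "human_2", w.paralog),
            ("chimp_1", "chimp_2", w.paralog),
            ("mouse_1", "mouse_2", w.paralog),
        ]
        return ScenarioResult(
            scenario, SimilarityGraph(genes, edges),
            expected_calls=frozenset(),
            restricted_expected={
                frozenset(("mouse", "rat")): frozenset(
                    {_pair("mouse", "mouse_1", "mouse_2")}
                ),
            },
        )
    raise InputError(
        f"unknown scenario {scenario!r}; expected fig1_full, fig1_no_rat or fig3_loss"
    )


SCENARIOS = ("fig1_full", "fig1_no_rat", "fig3_loss")


# ---------------------------------------------------------------------------
# Benchmark
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BenchmarkRecord:
    """Per-replicate result of the approximation-vs-heuristic comparison."""

    spec: GnpSpec
    replicate: int
    uncovered_approx: int
    uncovered_heuristic: int
    odd_paths: int
    n_isolated: int
    n_union_isolated: int
    runtime_approx_s: float
    runtime_heuristic_s: float

    def to_row(self) -> dict:
        return {
            "n": self.spec.n,
            "p": self.spec.edge_prob,
            "k": self.spec.k,
            "replicate": self.replicate,
            "seed": self.spec.seed,
            "uncovered_approx": self.uncovered_approx,
            "uncovered_heuristic": self.uncovered_heuristic,
            "odd_paths": self.odd_paths,
            "n_isolated": self.n_isolated,
            "n_union_isolated": self.n_union_isolated,
            "runtime_approx_s": self.runtime_approx_s,
            "runtime_heuristic_s": self.runtime_heuristic_s,
        }


def replicate_seed(base_seed: int, replicate: int) -> int:
    """Deterministic per-replicate seed below 2^31."""
    return int(
        np.random.SeedSequence([base_seed, replicate]).generate_state(1)[0]
        % _SEED_MOD
    )


def _count_isolated(graph: SimilarityGraph) -> int:
    g = graph.inter_subgraph()
    return sum(1 for v in g.nodes if g.degree[v] == 0)


def run_benchmark(
    specs: Sequence[GnpSpec],
    replicates: int = 20,
) -> tuple[list[BenchmarkRecord], pd.DataFrame]:
    """Run both cover algorithms on ``replicates`` fresh draws of each spec.

    Replicate seeds are derived from each spec's seed, so results are fully
    reproducible (runtimes aside).  Returns the per-replicate records and a
    per-spec aggregate of means.
    """
    if replicates < 1:
        raise ConfigError(f"replicates must be >= 1, got {replicates}")
    records = []
    for spec in specs:
        for rep in range(replicates):
            draw = replace(spec, seed=replicate_seed(spec.seed, rep))
            graph = gnp_colored_graph(draw)

            t0 = time.perf_counter()
            approx = approx_orec(graph)
            t_approx = time.perf_counter() - t0

            t0 = time.perf_counter()
            heur = heuristic_orec(graph)
            t_heur = time.perf_counter() - t0

            records.append(
                BenchmarkRecord(
                    spec=draw,
                    replicate=rep,
                    uncovered_approx=approx.n_uncovered,
                    uncovered_heuristic=heur.n_uncovered,
                    odd_paths=approx.odd_count or 0,
                    n_isolated=_count_isolated(graph),
                    n_union_isolated=approx.n_union_isolated or 0,
                    runtime_approx_s=t_approx,
                    runtime_heuristic_s=t_heur,
                )
            )
    frame = pd.DataFrame([r.to_row() for r in records])
    aggregate = (
        frame.groupby(["n", "p", "k"], as_index=False)
        .agg(
            mean_uncovered_approx=("uncovered_approx", "mean"),
            mean_uncovered_heuristic=("uncovered_heuristic", "mean"),
            mean_odd_paths=("odd_paths", "mean"),
            mean_isolated=("n_isolated", "mean"),
            mean_runtime_approx_s=("runtime_approx_s", "mean"),
            mean_runtime_heuristic_s=("runtime_heuristic_s", "mean"),
            replicates=("replicate", "count"),
        )
    )
    return records, aggregate


DEFAULT_COMPLETENESS_GRID = (0.0005, 0.001, 0.005, 0.01, 0.02, 0.05)


def default_benchmark_specs(
    n: int = 250,
    k: int = 5,
    completeness: Sequence[float] = DEFAULT_COMPLETENESS_GRID,
    seed: int = 0,
) -> list[GnpSpec]:
    """The scaled benchmark grid: n = 250 genes over k = 5 genomes across a
    completeness sweep, chosen to show the same sparse/dense regimes as a
    full-size run at a fraction of the cost."""
    return [GnpSpec(n=n, edge_prob=p, k=k, seed=seed) for p in completeness]
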
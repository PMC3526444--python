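# Methods

## Model

A similarity graph G = (V, E) has one vertex per gene, colored by genome
via c : V → genomes, and undirected edges weighted by percent similarity
w(e) ∈ [0, 100] from an all-vs-all homology search.  Genes descending from
the root or from one duplication event (an ortholog set) contain at most
one gene per genome, so orthology evidence corresponds to *orthogonal*
subgraphs: edge subsets whose connected components repeat no color.  The
package maximizes the number of vertices covered by such a subset
(MAX-OREC); uncovered vertices are genes that no orthology assignment can
explain and are therefore inparalog candidates.  Because covering is a
cardinality objective, the method is deliberately unweighted at the cover
stage — weights enter only through the input thresholds and the calling
rules.  The uncovered count is a *lower bound* on inparalogy: the cover
aggressively explains as many genes as possible by orthology.  For the
same reason the cover itself should not be read as an ortholog assignment.

## Input filters

* **Similarity thresholds**, inter-species 80 %, intra-species 70 % by
  default.  Comparison is inclusive (weight ≥ threshold kept); the choice
  between inclusive and exclusive is not observable at the default
  thresholds on typical inputs, and is configurable
  (`GraphConfig.inclusive_thresholds`).
* **Length-ratio filter**: a pair is discarded when one gene is more than
  1.25× longer than the other (configurable, `None` disables).  Lengths
  come from the metadata `length` column, falling back to
  `end − start + 1` on 1-based inclusive coordinates.
* **Reciprocal records** (a,b) and (b,a), possibly with asymmetric scores,
  collapse to one undirected edge carrying the maximum reported similarity
  (maximizes sensitivity; `min`/`mean` available).  Merging happens before
  thresholding.
* Genome labels are explicit, case-sensitive metadata; nothing is inferred
  from gene-id prefixes.  Strand is never used.

## The 2/3-approximation

1. For each genome x, compute a maximum-cardinality bipartite matching
   M(x) between color-x vertices and all others over inter-species edges
   (Hopcroft–Karp, implemented in-package over sorted adjacency lists so
   results are identical across processes).
2. R = ∪ₓ M(x) is 2-neighborhood-limited (2NL): a color-y neighbor of v
   can only arise from M(c(v)) or M(y), so each vertex has ≤ 2 neighbors
   of any one color.  |v(R)| upper-bounds every orthogonal cover.
3. Within the subgraph spanned by one unordered color pair every vertex
   has degree ≤ 2, so each color pair decomposes uniquely into simple
   paths and cycles whose vertices alternate between the two colors.
   Components with ≥ 3 vertices form the alternating structure set; P is
   the union of their edges.  A single edge is not counted as an
   alternating path — under the opposite reading P would equal R and the
   algorithm would degenerate to a bare matching, which provably cannot
   cover some graphs that have perfect orthogonal covers (a two-leaf,
   two-color star already defeats it).
4. Every alternating path or cycle is thinned to an every-other-edge
   matching of itself: even paths and cycles keep a perfect matching of
   their vertices; an odd path keeps a matching exposing exactly one
   even-position vertex.  These per-structure matchings are *not* combined
   into one global matching: structures of different color pairs may share
   a vertex, and the shared vertex may legitimately keep one edge of each
   — a constraint no single matching can express.  (A global maximum
   matching on (v(P), P) looks equivalent but is not: on instances with
   shared vertices it can expose two extra vertices on a graph with one —
   or zero — odd paths, breaking both stated guarantees.  Both failure
   modes were observed on random 7–15-vertex instances during
   development.)
5. The exposed vertex of each odd path is chosen deterministically among
   the path's even positions, preferring a vertex that remains covered
   anyway — through an edge of R \ P or through another alternating
   structure.  This preserves the worst-case bound (≤ 1 exposure per odd
   path) and in practice recovers most potential losses.
6. The kept edges are unioned with R \ P and a minimal perfect edge cover
   of the result is returned.  No vertex of that union has two neighbors
   of one color (such a pair of edges would itself be an alternating path,
   hence inside P and thinned), so the star components of the final cover
   repeat no color: the cover is orthogonal.

Guarantees: covered ≥ optimum − (number of odd alternating paths), and
covered > 2/3 · optimum; with no odd paths the cover is perfect on
non-isolated vertices.  All three are exercised against the exact oracle
in the test suite.

## Pairwise heuristic

Union of maximum bipartite matchings for every unordered genome pair,
then a minimal perfect edge cover.  Each pairwise matching contributes at
most one neighbor of each color to any vertex, so the stars are
orthogonal.  There is no approximation guarantee; its advantage is speed
(fewer, smaller matchings; no alternating-path machinery).  In the scaled
benchmark bundled here the approximation covers at least as many vertices
as the heuristic at every tested density while the heuristic runs roughly
2× faster; the heuristic's covering advantage reported for dense
full-scale graphs is an average-degree phenomenon that a 10×-smaller
vertex count at the same completeness grid does not reach.

## Minimal perfect edge cover

Per component with ≥ 2 vertices: a deterministic greedy maximal matching,
attachment of each unmatched vertex to its smallest neighbor (necessarily
matched), then removal, in sorted order, of any edge both of whose
endpoints stay covered without it.  The result touches every non-isolated
vertex, loses coverage if any edge is removed, and consists of stars.  A
maximum matching would also work but costs a blossom run per component;
minimality and the covered vertex set do not depend on the matching being
maximum.  Verified against brute force on every connected graph with ≤ 5
vertices.

## Exact oracle

Any orthogonal cover can be rewritten, without changing its covered
set, as vertex-disjoint stars whose center and leaves carry distinct
colors (maximal matching within each component plus attachments).  The
oracle therefore maximizes covered vertices over star packings by bitmask
dynamic programming per connected component of the inter-species graph,
enumerating candidate stars through the lowest uncovered vertex.  Guards:
at most `limit` inter-species edges (default 16) and 22 vertices per
component.  Intra-species edges are excluded up front — an intra edge's
endpoints share a color, so no orthogonal component can contain one.  The
test suite cross-checks the DP against an independent enumeration of all
edge subsets on small graphs.

## Inparalog calling

* **direct**: each uncovered gene pairs with its highest-weight *covered*
  same-genome neighbor (ties: smallest gene id).  Only intra-species edges
  qualify, so every supporting edge already passed the intra-species
  threshold.
* **chain** (default; generalizes direct): per genome, the subgraph of
  intra-species edges induced on the uncovered genes plus their covered
  same-genome neighbors; on each component containing an uncovered gene, a
  maximum-weight spanning tree (Kruskal; ties by weight descending then
  lexicographic edge), every tree edge touching an uncovered gene becomes
  a call.  Including the covered neighbors lets a duplication chain anchor
  to its covered progenitor; components with no covered anchor still
  produce calls among themselves.  An uncovered gene may appear in several
  calls (tree degree > 1).

Which genomes participate is chosen by the caller
(`restrict_to_species`); no species tree is required.  Considering more
genomes is what makes the calls robust to loss: the bundled `fig3_loss`
scenario shows a pair-only {mouse, rat} analysis fabricating a false
mouse pair that the four-genome analysis avoids.

## Synthetic data

* **Colored G(n, p)**: each of the n(n−1)/2 pairs receives an edge
  independently with probability p; colors are assigned round-robin so the
  k genomes are balanced (uniform-random assignment available); weights
  are constant at 100 because the cover stage is unweighted.  Same-color
  edges are kept as intra-species edges but are invisible to the cover
  algorithms.  These graphs exercise the covering machinery only — they
  have no gene histories, no coordinates, and edge probabilities
  independent of any evolutionary distance, so benchmark results say
  nothing about calling accuracy on real genomes.
* **History scenarios** (`fig1_full`, `fig1_no_rat`, `fig3_loss`): small
  duplication/speciation/loss histories over human, chimp, mouse and rat
  emitted as similarity graphs with ground-truth calls.  Ortholog edges
  carry 96 %, surviving cross-copy edges 85 %, within-genome paralog
  edges 88 % — orthologs slightly above paralogs, everything above the
  default thresholds; cross-copy similarity toward the primates in
  `fig1_full` is taken to have decayed below the 80 % threshold, which is
  what makes the rat-removed variant informative.  Scenario genes carry
  coordinates (two copies 28 kbp apart on one chromosome) so the
  distance classification is exercised end to end.

## Benchmark scale

The bundled sweep uses n = 250 genes, k = 5 genomes, 20 replicates per
completeness in {0.05, 0.1, 0.5, 1, 2, 5} % — small enough for a default
test run, dense enough to show both algorithms' behavior; a full-size run
(n = 2500, 100 replicates) sits behind `--full`.  Per-replicate seeds
derive deterministically from the spec seed; identical seeds give
byte-identical records apart from runtimes.  Reported uncovered counts
include vertices isolated in the input graph (identical for both
algorithms); records also carry the count of vertices untouched by the
union of per-color matchings, since odd paths plus *that* count — not the
input-isolated count — is what bounds the approximation's uncovered
vertices.

## Distance and similarity classes

Distance is the gap between gene intervals (0 when overlapping; midpoint
distance behind a flag): `near` < 50 kbp on one chromosome, `far`
otherwise on one chromosome (a gap of exactly 50 kbp is far), `unlinked`
across chromosomes, `unknown` when coordinates are missing.  Similarity
uses four right-closed bins over three ascending boundaries; only the top
boundary (95 %, "recent" pairs strictly above it) is biologically
anchored — the defaults 85/90 for the lower two are this package's
choice and are freely configurable.  Proportions are per genome over
known-distance calls; unknown-distance calls are tabulated separately.

## Numerical and degenerate-input choices

* All tie-breaks are lexicographic on sorted gene ids; no randomness at
  cover time, so every result is reproducible across processes (one
  library matching routine was replaced in-package for exactly this
  reason).
* Edge weights round-trip through text serialization at full float
  precision (`repr`).
* Empty graphs, edgeless graphs, single-genome graphs and covers covering
  everything all yield empty-but-well-formed outputs rather than errors.
* Exit codes of the CLI: 0 success, 2 input error, 3 configuration error;
  logs on stderr, data only in named files.

## Known limitations

* The approximation guarantee is about vertex counts, not about which
  genes are covered; biological plausibility of individual assignments is
  not modeled.
* Calling depends on the cover: a different optimal cover can move a call
  between members of one duplication chain.
* No reconciliation against gene trees, no outparalog classification, no
  ortholog reporting, and no mechanistic attribution of individual pairs
  to tandem/retro/drift duplication — the classification tables only
  profile class proportions.
* The G(n, p) benchmark measures covering behavior, not calling accuracy;
  see above.
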
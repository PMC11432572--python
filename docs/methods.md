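# Methods

## The network model

The object of analysis is an undirected, unweighted molecular interaction
network. Nodes are molecule identifiers (trimmed of surrounding whitespace,
compared case-sensitively: curated molecule names are case-meaningful);
edges are curated interaction records carrying a free-text interaction type
and optional literature provenance. Two layers coexist deliberately:

* **edge records** — the curated list, preserved verbatim including
  duplicate statements of the same interaction and self-interactions;
* **simple adjacency** — the graph used for every topological computation,
  with self-loops dropped and duplicates collapsed.

The split is not cosmetic. Shortest-path betweenness is only well defined on
networks without multiple edges, and a curated link count routinely exceeds
the distinct-neighbor-pair count precisely because of duplicates and
self-loops; keeping both layers lets the reported "number of edges" remain
the curated record count while the mean-neighbor statistic and all
centralities are computed on the simple graph. Interaction types never
weight an edge and direction is never used.

## Distances and path counts

All ten node metrics derive from one all-pairs BFS that produces the hop
distance matrix and the matrix σ(s,t) of *counts of distinct shortest
paths* (σ is accumulated along BFS levels, as in Brandes' algorithm).
Betweenness and stress are then evaluated directly from the defining sums,
using the identity σ_st(v) = σ_sv · σ_vt whenever
d(s,v) + d(v,t) = d(s,t):

* betweenness: Σ_{s≠v≠t} σ_st(v)/σ_st over unordered pairs, divided by
  (N−1)(N−2)/2 where N is the size of v's connected component (so values
  lie in [0,1] even on disconnected inputs; nodes in components of fewer
  than three nodes score 0);
* stress: the same sum without the σ_st denominator, an integer;
* closeness: reciprocal of the mean distance to *reachable* nodes
  (0 for isolated nodes);
* eccentricity: maximum reachable distance;
* radiality: (D_c + 1 − avgL(n)) / D_c with D_c the component diameter.

Unreachable pairs are excluded from every average rather than assigned an
infinite distance. On a single-component network this choice is invisible;
on fragmented inputs it keeps all metrics finite and component-local.

Clustering (CI = 2n_I/(k_I(k_I−1)), 0 for degree < 2), neighborhood
connectivity (mean neighbor degree) and the topological coefficient
(T(n) = mean over nodes m sharing ≥ 1 neighbor of J(n,m), divided by
degree(n), with J = shared-neighbor count plus 1 for a direct n–m edge)
are neighborhood-local. T(n) is evaluated for any node with a non-empty
two-step neighborhood, including degree-1 nodes (a pendant vertex of a path
scores 1.0); nodes with no shared-neighbor partner score 0. The network
clustering coefficient averages CI over **all** nodes by default; a
`clustering_min_degree=2` option restricts the average to nodes with at
least two neighbors, since network-analysis tools differ on this convention
and the choice moves the value noticeably on sparse networks.

The direct evaluation of the betweenness/stress sums is O(n³) with small
vectorized constants — a deliberate trade of asymptotics for transparency.
It is instantaneous at the few-hundred-node scale these curated networks
occupy; networkx's Brandes implementation is used in the test suite as an
independent cross-check, never as the implementation.

## Scale-free classification

Two conditions define the Barabási–Albert regime here:

1. the degree distribution follows a power law N(k) = a·k^γ. The fit is
   ordinary least squares on (log₁₀ k, log₁₀ N(k)) using **raw counts**
   (no probabilities, no log-binning), skipping degrees with zero count;
   a = 10^intercept, γ = slope, with Pearson r and R² = r² reported on the
   logged data. This is the classical straight-line-on-log-log criterion,
   not maximum-likelihood (Clauset-style) estimation with x_min selection —
   deliberately, because the straight-line fit is what the standard
   network-analyzer toolchain reports and what the R²-based verdict needs;
2. the clustering coefficient is uncorrelated with degree: R² of an
   untransformed OLS of CI on ND across all nodes of degree ≥ 1.

The verdict is `fit R² ≥ 0.6` AND `independence R² ≤ 0.1` AND at least one
hub present. Published analyses report exemplar values (fit R² near 0.7,
independence R² near 0.002) rather than cutoffs; the defaults bracket those
exemplars with margin, are configurable, and are echoed in every assessment
object so a verdict is reproducible from its own report. A degree-regular
graph, which offers fewer than two support points, receives a degenerate
flat fit with R² = 0 and therefore a negative verdict rather than an error.

## Hubs and bottlenecks

**Hubs**: ND > μ + σ, strict. σ is the *sample* standard deviation
(n−1 denominator) by default; the population convention is available and the
policy is recorded in the report, since the defining rule is silent on the
denominator and the two can disagree near the threshold.

**Bottlenecks**: for every root s, a breadth-first shortest-path tree T_s is
built; p_s(v) = 1 when more than |V(T_s)|/4 of the root-to-node paths of
T_s contain v, and BN(v) = Σ_s p_s(v). In a tree each node t ≠ s defines
exactly one root-to-t path, and the paths containing v are exactly those
ending in v's subtree — so the count reduces to v's subtree size.
Two policies are explicit:

* *tie-break*: BFS trees are not unique; each node's parent is its
  lexicographically smallest neighbor on the previous level, making BN
  deterministic and relabeling-consistent (and irrelevant on trees, where
  T_s is unique).
* *endpoint semantics*: whether the path ending at v itself "meets" v. The
  default counts it (count = subtree size, so every reachable non-root node
  can contribute); `count_endpoint=False` counts strictly interior
  memberships (subtree size − 1). The default matches the behavior of the
  established bottleneck implementations; the switch exists because the
  formula alone does not decide it, and the choice is visible on very small
  trees (in a 3-node path the quarter threshold is 0.75, so the leaf score
  hinges on it).

## PCA outliers

The feature matrix is nodes × the ten metrics, in a fixed column order,
restricted to the largest connected component (path-length scales are not
comparable across fragments). Because the metrics live on wildly different
scales (stress is an unbounded count, closeness sits in [0,1]), the default
is correlation-matrix PCA: columns are centered and scaled to unit sample
variance before the decomposition (covariance mode via
`standardize=False`). Zero-variance columns are dropped from the
decomposition and reported. Component signs follow a deterministic
convention (largest-magnitude loading positive).

A node is an outlier when its (PC1, PC2) score lies outside the chi-square
confidence ellipse: squared Mahalanobis distance under the 2-D score
covariance beyond the χ²(2) quantile at the chosen confidence (default
0.95, configurable and recorded). With a bivariate-normal score cloud the
ellipse would contain 95 % of nodes; on real centrality data the flagged
set is the heavy tail — hubs and receptor-like molecules whose combination
of centralities separates them from the bulk.

## Synthetic generators

`generate_ba(n, m, seed)` is textbook preferential attachment growing from
an m-clique (from a single edge when m = 1, since attachment needs an edge
to start from); it is the positive control the classifier must accept.

`generate_afirnet_like(seed)` emulates the *global statistics* of a curated
AGE/fertility/immunity network rather than any particular edge list: 145
nodes, 258 distinct links plus one duplicate and one self-loop record
(260 records), one connected component, mean degree 3.56, a decaying degree
distribution, exactly one hub, and three compartment labels
(glycemic_control 55, fertility 50, immunity 40) with named analogue
molecules (TRPV1 as the designated fertility hub; AGE, RAGE, CML as
high-degree glycemic bridges). The construction realizes an exact engineered
degree sequence — hub degree 30, tail counts {k=1: 26, 2: 26, 3: 26, 4: 22,
5: 22, 6: 22} — via Havel–Hakimi, patches it to one component with
degree-preserving edge crossings, and randomizes wiring with seeded
connected double-edge swaps. The sequence was chosen analytically: its
μ + σ is 6.3497, strictly between the largest ordinary degree (6) and the
hub degree (30), so hub detection finds exactly one hub for *every* seed;
and the log–log fit over its eight support points has R² ≈ 0.73 with
γ ≈ −0.97, comfortably past the verdict thresholds.

What the emulation does **not** reproduce: the true curated degree sequence
and edge list, literature provenance, biologically meaningful wiring within
and between compartments (compartments are labels, not wired modules), and
the exact printed summary statistics of the published network (diameter,
characteristic path length and the fitted exponent differ, since randomized
wiring at this density is more compact than the curated topology). Passing
tests on the emulation therefore demonstrate that the *pipeline machinery*
is correct and deterministic, not that any biological conclusion about real
data is reproduced.

Against the real curated workbook (when available to a user), the expected
manual checks are: 145 nodes and 262 records with one component; mean
neighbors 3.586; clustering 0.023; diameter 16; characteristic path length
5.453; fit a ≈ 29.69, γ ≈ −1.276 (r 0.8303, R² 0.6894); degree–clustering
R² ≈ 0.0017; hub set exactly {TRPV1}; and TRPV1 third in the bottleneck
ranking behind RAGE and CML. The workbook ingestion path itself is exercised
end-to-end in the test suite with a synthetically written five-sheet
workbook.

## Numerical and degenerate-input choices

* Distances/σ in float64; σ is exact for the path counts reachable at these
  network sizes (integers ≤ 2⁵³).
* Stress is rounded to int after the float accumulation.
* Isolated nodes: closeness, radiality, eccentricity, average path length,
  neighborhood connectivity and topological coefficient all 0.
* Empty networks: summary raises; degree distribution returns empty; hub
  detection requires ≥ 2 nodes; PCA requires ≥ 3 rows and ≥ 2 non-constant
  columns.
* The power-law fitter requires ≥ 2 distinct degrees and raises otherwise
  (the classifier converts that into a failing verdict).
* Pipeline outputs are byte-deterministic for a fixed config and input;
  every run writes its resolved configuration and a stage manifest.

## Problem sizes used in the checked examples

The test suite and the acceptance script run the full pipeline on the
145-node emulation, the classifier on a 1000-node Barabási–Albert network,
and the exhaustive-enumeration oracle on 100 (suite) / 50 (script) random
connected graphs of 3–8 nodes — sizes at which all-simple-path enumeration
is exact and fast, chosen so the whole validation is a matter of seconds.
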
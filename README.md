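# afirnet

Topological analysis of curated molecular interaction networks.

Systems-biology studies of processes such as advanced glycation end product
(AGE) signalling — where glycemic control, fertility and immune regulation
intersect through molecules like RAGE, CML and the TRPV1 ion channel — often
proceed by curating every literature-supported interaction into a database,
building an undirected molecular network from it, and asking structural
questions: Is the network scale-free? Which molecules are hubs? Which control
the flow of information as bottlenecks? Which combine their centralities in a
way that sets them apart from everything else?

`afirnet` makes that whole workflow one reproducible library/CLI instead of a
chain of GUI tools. It is aimed at molecular and systems biologists who have
a curated edge list (workbook, CSV/TSV or SIF) and want the standard
topological read-out with every convention explicit.

## What it computes

* **Ten node-level metrics** (unweighted, undirected hop distances): degree
  *ND*; clustering coefficient *CI = 2n_I / (k_I (k_I − 1))*; betweenness
  *C_b(n) = Σ_{s≠n≠t} σ_st(n)/σ_st* normalized by *(N−1)(N−2)/2* per
  connected component; closeness *C_c(n) = 1 / avg L(n,m)*; average shortest
  path length; eccentricity; radiality; stress; neighborhood connectivity;
  topological coefficient.
* **Network summary**: components, node/edge counts, mean neighbors,
  network clustering coefficient, diameter, characteristic path length.
* **Scale-free classification**: ordinary least squares on the base-10
  logged degree distribution, *N(k) = a·k^γ*, with Pearson *r* and *R²*;
  the degree–clustering independence *R²*; hub presence — combined into a
  Barabási–Albert verdict with explicit, configurable thresholds.
* **Key nodes**: hubs by the strict rule *ND > μ + σ*; bottleneck scores
  *BN(v) = Σ_s p_s(v)*, where *p_s(v) = 1* when more than *|V(T_s)|/4*
  root-to-node paths of the shortest-path tree *T_s* pass through *v*.
* **PCA outliers**: correlation-matrix PCA over the node × ten-metric
  matrix; nodes outside the chi-square confidence ellipse of the PC1–PC2
  scores are flagged.
* **Synthetic generators**: Barabási–Albert networks, closed-form test
  fixtures, and a 145-node emulation of a curated AGE/fertility/immunity
  network (three labeled compartments, ~260 interaction records including a
  duplicate and a self-loop, exactly one engineered hub) so the entire
  pipeline is testable with no external data.

Interaction records are never discarded: duplicates and self-loops stay in
the record list, while the *simple adjacency* used by all metrics collapses
them (shortest-path centralities are only defined on multigraph-free
networks).

## Worked example

Generate the emulated curated network and analyze it:

```bash
afirnet generate --kind afirnet_like --seed 1 --out demo.sif
# wrote 145 nodes / 260 records to demo.sif
afirnet analyze --input demo.sif --out demo_results
```

which prints:

```
Connected components	1
Number of nodes	145
Number of edges	260
Averaged number of neighbors	3.5586206896551724
Clustering coefficient	0.05237415774871185
Network diameter	8
Characteristic path length	3.8026819923371646

Power-law fit: N(k) = 60.27 * k^-0.9664 (r = -0.8521, R^2 = 0.7260)
Degree-clustering R^2 = 0.008372
Scale-free verdict: True (fit R^2 >= 0.6, independence R^2 <= 0.1, hubs present = True)

Hubs (ND > mu + sigma = 6.350; sigma policy: sample): TRPV1 (ND=30)
Top bottlenecks (tree policy: bfs-smallest-identifier-parent; endpoint counted: True): TRPV1 (BN=110), IM-001 (BN=10), ...
PCA outliers (95% ellipse): TRPV1, GC-002
```

Reading this: the network is one connected component of 145 molecules and
260 interaction records (258 distinct links — one duplicate and one
self-loop are kept at the record level only), with a mean of 3.56 distinct
neighbors per node. The degree distribution falls on a decaying power law
(*R² = 0.73* on logged data) while clustering is independent of degree
(*R² = 0.008*), so the network passes both scale-free conditions. Exactly one
molecule exceeds the hub threshold μ + σ = 6.35, the designated hub analogue
TRPV1 (30 neighbors); it also dominates the bottleneck ranking and falls far
outside the 95 % PCA ellipse — a molecule whose removal would fragment
information flow.

`demo_results/` then contains the full bundle: `node_metrics.csv` (ten
metrics per node), `summary.csv`, `degree_distribution.csv`,
`scale_free.csv`, `hubs.csv`, `bottlenecks.csv`, the PCA scores/loadings/
variance/outlier CSVs, SIF and GraphML exports, the resolved `config.yaml`
and a stage `MANIFEST`.

The same `analyze` command accepts a curated workbook
(`--input database.xlsx`) with sheets `ages`, `receptors`, an interaction
sheet such as `AGE–TRPV1`, `analysis` and `reference`, or a flat CSV/TSV
edge list. The library surface mirrors the CLI:

```python
import afirnet as af

net = af.generate_afirnet_like(seed=1)
metrics = af.compute_node_metrics(net)        # 145 x 10 DataFrame
af.find_hubs(net).hubs                        # [("TRPV1", 30)]
af.classify_scale_free(net).verdict           # True
```

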
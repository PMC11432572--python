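"""Shortest-path structure and the ten node-level topological metrics.

All distances are unweighted hop counts on the simple adjacency (undirected,
self-loops and duplicate records excluded).  One breadth-first sweep per node
yields the full distance matrix together with the shortest-path count matrix
sigma[s, t]; every path-based metric (betweenness, stress, closeness, average
shortest path length, eccentricity, radiality) is then derived from those two
matrices so the metrics are mutually consistent by construction.

Definitions
-----------
degree
    Number of distinct neighbors.
clustering coefficient
    CI = 2 nI / (kI (kI - 1)) where nI counts links among the kI neighbors;
    0 for degree < 2.
betweenness centrality
    sum over s != n != t of sigma_st(n) / sigma_st, normalized by
    (N - 1)(N - 2) / 2 with N the size of n's connected component, so
    Cb in [0, 1].
closeness centrality
    Cc(n) = 1 / avg(L(n, m)) over nodes m reachable from n; 0 for an
    isolated node.
stress
    Number of shortest paths (over unordered pairs s < t, s != n != t) on
    which n lies as an interior vertex.
radiality
    (D_c + 1 - avg(L(n, m))) / D_c with D_c the diameter of n's component.
neighborhood connectivity
    Mean degree of n's neighbors.
topological coefficient
    T(n) = avg_m J(n, m) / degree(n) over nodes m sharing at least one
    neighbor with n, where J(n, m) = |shared neighbors| plus 1 if n and m
    are directly linked.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .netio import MolecularNetwork

#: fixed column order of the node-metric table (also the PCA feature order)
METRIC_COLUMNS = [
    "average_shortest_path_length",
    "betweenness",
    "closeness",
    "clustering_coefficient",
    "degree",
    "eccentricity",
    "neighborhood_connectivity",
    "radiality",
    "stress",
    "topological_coefficient",
]


@dataclass
class ShortestPathData:
    """All-pairs BFS result: distances and shortest-path counts."""

    nodes: list[str]
    index: dict[str, int]
    dist: np.ndarray  #: (n, n) hop counts, np.inf for unreachable pairs
    sigma: np.ndarray  #: (n, n) number of distinct shortest paths, 0 if unreachable

    def sigma_through(self, s: str, t: str, n: str) -> float:
        """sigma_st(n): shortest s-t paths passing through n (n may be an endpoint)."""
        i, j, k = self.index[s], self.index[t], self.index[n]
        d = self.dist[i, j]
        if not np.isfinite(d):
            return 0.0
        if self.dist[i, k] + self.dist[k, j] != d:
            return 0.0
        if k == i or k == j:
            return self.sigma[i, j]
        return self.sigma[i, k] * self.sigma[k, j]


@dataclass
class NetworkSummary:
    """Global topological parameters of a network."""

    connected_components: int
    num_nodes: int
    num_edge_records: int
    avg_neighbors: float
    network_clustering_coefficient: float
    diameter: int
    characteristic_path_length: float


def all_pairs_shortest_paths(net: MolecularNetwork) -> ShortestPathData:
    """BFS from every node, counting all distinct shortest paths.

    Unreachable pairs get distance ``inf`` and sigma 0; the diagonal is
    distance 0 with sigma 1 (the empty path).
    """
    g = net.graph
    nodes = list(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    adj = [[index[m] for m in g[v]] for v in nodes]
    for s in range(n):
        dist[s, s] = 0.0
        sigma[s, s] = 1.0
        queue = [s]
        while queue:
            nxt = []
            for v in queue:
                dv = dist[s, v]
                for w in adj[v]:
                    if not np.isfinite(dist[s, w]):
                        dist[s, w] = dv + 1
                        nxt.append(w)
                    if dist[s, w] == dv + 1:
                        sigma[s, w] += sigma[s, v]
            queue = nxt
    return ShortestPathData(nodes, index, dist, sigma)


def _component_sizes_and_diameters(sp: ShortestPathData) -> tuple[np.ndarray, np.ndarray]:
    """Per-node component size and component diameter from the distance matrix."""
    n = len(sp.nodes)
    finite = np.isfinite(sp.dist)
    sizes = finite.sum(axis=1)  # includes the node itself
    diam = np.where(finite, sp.dist, 0.0).max(axis=1)
    return sizes, diam


def node_clustering(net: MolecularNetwork, n: str) -> float:
    """CI = 2 nI / (kI (kI - 1)); 0 for fewer than two neighbors."""
    return float(nx.clustering(net.graph, n))


def _interior_path_terms(sp: ShortestPathData, v: int) -> tuple[np.ndarray, np.ndarray]:
    """For node v: matrices of sigma_st(v) (interior only) and sigma_st over valid (s, t)."""
    d = sp.dist
    n = d.shape[0]
    on_path = (d[:, v][:, None] + d[v, :][None, :]) == d
    finite = np.isfinite(d)
    valid = on_path & finite
    valid[v, :] = False
    valid[:, v] = False
    np.fill_diagonal(valid, False)
    through = np.where(valid, sp.sigma[:, v][:, None] * sp.sigma[v, :][None, :], 0.0)
    totals = np.where(valid, sp.sigma, 1.0)
    return through, totals


def betweenness_centrality(
    net: MolecularNetwork, sp: ShortestPathData | None = None
) -> dict[str, float]:
    """Normalized shortest-path betweenness, per connected component.

    The raw sum over pairs s != n != t of sigma_st(n)/sigma_st is divided by
    (N - 1)(N - 2)/2 where N is the node count of n's component, so every
    value lies in [0, 1]; nodes in components smaller than 3 score 0.
    """
    sp = sp or all_pairs_shortest_paths(net)
    sizes, _ = _component_sizes_and_diameters(sp)
    out = {}
    for v, name in enumerate(sp.nodes):
        nc = sizes[v]
        if nc < 3:
            out[name] = 0.0
            continue
        through, totals = _interior_path_terms(sp, v)
        raw = (through / totals).sum() / 2.0  # each unordered pair counted twice
        out[name] = float(raw / ((nc - 1) * (nc - 2) / 2.0))
    return out


def stress_centrality(
    net: MolecularNetwork, sp: ShortestPathData | None = None
) -> dict[str, int]:
    """Count of shortest paths (unordered endpoint pairs) with n interior."""
    sp = sp or all_pairs_shortest_paths(net)
    out = {}
    for v, name in enumerate(sp.nodes):
        through, _ = _interior_path_terms(sp, v)
        out[name] = int(round(through.sum() / 2.0))
    return out


def closeness_centrality(
    net: MolecularNetwork, sp: ShortestPathData | None = None
) -> dict[str, float]:
    """Cc(n) = 1 / avg(L(n, m)) over reachable m; isolated nodes score 0."""
    sp = sp or all_pairs_shortest_paths(net)
    out = {}
    for v, name in enumerate(sp.nodes):
        row = sp.dist[v]
        reach = np.isfinite(row) & (row > 0)
        out[name] = float(reach.sum() / row[reach].sum()) if reach.any() else 0.0
    return out


def average_shortest_path_lengths(
    net: MolecularNetwork, sp: ShortestPathData | None = None
) -> dict[str, float]:
    """Mean hop distance from each node to its reachable peers (0 if isolated)."""
    sp = sp or all_pairs_shortest_paths(net)
    out = {}
    for v, name in enumerate(sp.nodes):
        row = sp.dist[v]
        reach = np.isfinite(row) & (row > 0)
        out[name] = float(row[reach].mean()) if reach.any() else 0.0
    return out


def eccentricity_radiality(
    net: MolecularNetwork, sp: ShortestPathData | None = None
) -> tuple[dict[str, int], dict[str, float]]:
    """Eccentricity (max reachable distance) and radiality per node.

    Radiality is (D_c + 1 - avgL(n)) / D_c with D_c the diameter of n's
    component; nodes in singleton or edgeless components score 0.
    """
    sp = sp or all_pairs_shortest_paths(net)
    _, diam = _component_sizes_and_diameters(sp)
    ecc, rad = {}, {}
    for v, name in enumerate(sp.nodes):
        row = sp.dist[v]
        reach = np.isfinite(row) & (row > 0)
        if not reach.any():
            ecc[name], rad[name] = 0, 0.0
            continue
        ecc[name] = int(row[reach].max())
        dc = diam[v]
        rad[name] = float((dc + 1 - row[reach].mean()) / dc)
    return ecc, rad


def neighborhood_connectivity(net: MolecularNetwork) -> dict[str, float]:
    """Mean degree of each node's neighbors (0 for isolated nodes)."""
    g = net.graph
    out = {}
    for n in g:
        nbrs = list(g[n])
        out[n] = float(np.mean([g.degree[m] for m in nbrs])) if nbrs else 0.0
    return out


def topological_coefficient(net: MolecularNetwork) -> dict[str, float]:
    """T(n): shared-neighbor overlap averaged over n's two-step neighborhood.

    J(n, m) counts neighbors shared by n and m, plus one when n-m is itself
    an edge; T(n) is the mean J over all m sharing at least one neighbor
    with n, divided by n's degree.  Nodes with no such m score 0.
    """
    g = net.graph
    nbrs = {n: set(g[n]) for n in g}
    out = {}
    for n in g:
        kn = len(nbrs[n])
        if kn == 0:
            out[n] = 0.0
            continue
        js = []
        for m in g:
            if m == n:
                continue
            shared = len(nbrs[n] & nbrs[m])
            if shared == 0:
                continue
            js.append(shared + (1 if g.has_edge(n, m) else 0))
        out[n] = float(np.mean(js) / kn) if js else 0.0
    return out


def compute_node_metrics(
    net: MolecularNetwork, sp: ShortestPathData | None = None
) -> pd.DataFrame:
    """The full node x ten-metric table, columns in :data:`METRIC_COLUMNS` order."""
    sp = sp or all_pairs_shortest_paths(net)
    ecc, rad = eccentricity_radiality(net, sp)
    clustering = nx.clustering(net.graph)
    frame = pd.DataFrame(
        {
            "average_shortest_path_length": average_shortest_path_lengths(net, sp),
            "betweenness": betweenness_centrality(net, sp),
            "closeness": closeness_centrality(net, sp),
            "clustering_coefficient": {n: float(c) for n, c in clustering.items()},
            "degree": {n: net.degree(n) for n in net.nodes},
            "eccentricity": ecc,
            "neighborhood_connectivity": neighborhood_connectivity(net),
            "radiality": rad,
            "stress": stress_centrality(net, sp),
            "topological_coefficient": topological_coefficient(net),
        }
    )
    return frame.loc[sp.nodes, METRIC_COLUMNS]


def network_summary(
    net: MolecularNetwork,
    sp: ShortestPathData | None = None,
    clustering_min_degree: int = 0,
) -> NetworkSummary:
    """Global summary statistics.

    ``clustering_min_degree=2`` averages the clustering coefficient over
    nodes with at least two neighbors only (an alternative convention some
    network-analysis tools use); the default averages over all nodes.
    """
    if net.num_nodes == 0:
        raise ValueError("cannot summarize an empty network")
    sp = sp or all_pairs_shortest_paths(net)
    finite = np.isfinite(sp.dist)
    off = finite & (sp.dist > 0)
    iu = np.triu_indices(len(sp.nodes), k=1)
    pair_d = sp.dist[iu][off[iu]]
    cpl = float(pair_d.mean()) if pair_d.size else 0.0
    diam = int(pair_d.max()) if pair_d.size else 0
    ci = nx.clustering(net.graph)
    degs = dict(net.graph.degree)
    cvals = [c for n, c in ci.items() if degs[n] >= clustering_min_degree]
    return NetworkSummary(
        connected_components=nx.number_connected_components(net.graph),
        num_nodes=net.num_nodes,
        num_edge_records=net.num_edge_records,
        avg_neighbors=float(np.mean(list(degs.values()))),
        network_clustering_coefficient=float(np.mean(cvals)) if cvals else 0.0,
        diameter=diam,
        characteristic_path_length=cpl,
    )
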
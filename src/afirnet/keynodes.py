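"""Key-node detection: hubs by the degree rule, bottlenecks by shortest-path trees.

Hubs are the hyper-connected nodes: ND > mu + sigma, where mu and sigma are
the mean and standard deviation of the node degree over the whole network
(strict inequality, so a degree-regular network has no hubs).

The bottleneck score of node v is BN(v) = sum over roots s of p_s(v), where
p_s(v) = 1 exactly when more than |V(T_s)|/4 of the root-to-node paths of the
shortest path tree T_s rooted at s pass through v.  In a tree, every path
from s through v ends in v's subtree, so the count of paths containing v is
simply the size of v's subtree (v itself included when the endpoint counts as
"meeting at v", the default).  High BN marks nodes that control information
flow between network regions.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .netio import MolecularNetwork


@dataclass
class HubReport:
    """Degree statistics and the nodes exceeding the mu + sigma threshold."""

    mu: float
    sigma: float
    threshold: float
    hubs: list[tuple[str, int]]  #: (node, degree), descending degree
    sigma_policy: str  #: "sample" (n-1 denominator) or "population"


@dataclass
class BottleneckReport:
    """BN scores with their ranking and the tree policies that produced them."""

    scores: dict[str, int]
    ranking: list[tuple[str, int]]  #: descending BN, ties by node identifier
    tree_policy: str
    count_endpoint: bool


def find_hubs(net: MolecularNetwork, sigma_policy: str = "sample") -> HubReport:
    """Nodes whose degree strictly exceeds mean + one standard deviation."""
    degs = {n: net.degree(n) for n in net.nodes}
    if len(degs) < 2:
        raise ValueError("hub detection needs at least two nodes")
    vals = np.array(list(degs.values()), dtype=float)
    mu = float(vals.mean())
    ddof = 1 if sigma_policy == "sample" else 0
    sigma = float(vals.std(ddof=ddof))
    threshold = mu + sigma
    hubs = sorted(
        ((n, d) for n, d in degs.items() if d > threshold),
        key=lambda nd: (-nd[1], nd[0]),
    )
    return HubReport(mu, sigma, threshold, hubs, sigma_policy)


def shortest_path_tree(net: MolecularNetwork, s: str) -> dict[str, str]:
    """Deterministic BFS shortest-path tree over s's component.

    Returns a parent map (root excluded).  BFS trees are not unique; ties
    are broken by giving each node the lexicographically smallest neighbor
    on the previous level as its parent, so the tree — and every score
    derived from it — is reproducible.
    """
    g = net.graph
    if s not in g:
        raise KeyError(s)
    level = {s: 0}
    parent: dict[str, str] = {}
    queue = deque([s])
    while queue:
        v = queue.popleft()
        for w in sorted(g[v]):
            if w not in level:
                level[w] = level[v] + 1
                parent[w] = v
                queue.append(w)
            elif level[w] == level[v] + 1 and v < parent[w]:
                parent[w] = v
    return parent


def _subtree_sizes(parent: dict[str, str], root: str) -> dict[str, int]:
    """Size of each node's subtree in the rooted tree (node itself included)."""
    children: dict[str, list[str]] = {root: []}
    for c, p in parent.items():
        children.setdefault(c, [])
        children.setdefault(p, []).append(c)
    size = {}
    # iterative post-order
    stack = [(root, False)]
    while stack:
        v, done = stack.pop()
        if done:
            size[v] = 1 + sum(size[c] for c in children[v])
        else:
            stack.append((v, True))
            stack.extend((c, False) for c in children[v])
    return size


def bottleneck_scores(
    net: MolecularNetwork, count_endpoint: bool = True
) -> BottleneckReport:
    """BN(v) over every choice of shortest-path-tree root.

    For root s, the number of root-to-node paths of T_s containing v equals
    v's subtree size; with ``count_endpoint=False`` the path ending at v
    itself is not counted (v only "meets" paths as an interior vertex).
    p_s(v) = 1 when that count exceeds |V(T_s)|/4; the root never scores
    from its own tree.
    """
    scores = {n: 0 for n in net.nodes}
    for s in net.nodes:
        parent = shortest_path_tree(net, s)
        tree_nodes = len(parent) + 1
        if tree_nodes == 1:
            continue
        size = _subtree_sizes(parent, s)
        quarter = tree_nodes / 4.0
        for v in parent:  # every non-root node of T_s
            count = size[v] if count_endpoint else size[v] - 1
            if count > quarter:
                scores[v] += 1
    ranking = sorted(scores.items(), key=lambda nv: (-nv[1], nv[0]))
    return BottleneckReport(
        scores=scores,
        ranking=ranking,
        tree_policy="bfs-smallest-identifier-parent",
        count_endpoint=count_endpoint,
    )
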
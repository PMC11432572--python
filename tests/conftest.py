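"""Shared fixtures and the exhaustive shortest-path oracle.

The oracle enumerates *all simple paths* between every node pair, keeps the
shortest ones, and derives distances, path counts, betweenness, closeness
and stress directly from that enumeration — a completely independent route
from the BFS/matrix implementation under test, feasible on graphs of up to
~8 nodes.
"""

from __future__ import annotations

import itertools
import random

import networkx as nx
import pytest

from afirnet.netio import InteractionRecord, MolecularNetwork


def net_from_edges(edges, nodes=()) -> MolecularNetwork:
    return MolecularNetwork(
        [InteractionRecord(str(u), str(v), "interacts") for u, v in edges],
        nodes=[str(n) for n in nodes],
    )


def random_connected_network(seed: int, max_nodes: int = 8) -> MolecularNetwork:
    """Seeded random connected graph with 3..max_nodes nodes."""
    rng = random.Random(seed)
    n = rng.randint(3, max_nodes)
    p = rng.uniform(0.3, 0.8)
    while True:
        g = nx.gnp_random_graph(n, p, seed=rng.randint(0, 2**31 - 1))
        if g.number_of_edges() and nx.is_connected(g):
            return net_from_edges(g.edges())


def enumerate_shortest_paths(net: MolecularNetwork):
    """All shortest paths per unordered pair, by brute-force simple-path search.

    Returns ``(dist, paths)`` where ``paths[(s, t)]`` is the list of all
    shortest s-t node sequences and ``dist[(s, t)]`` their hop length.
    """
    g = net.graph
    dist, paths = {}, {}
    for s, t in itertools.combinations(sorted(g.nodes), 2):
        simple = list(nx.all_simple_paths(g, s, t))
        if not simple:
            continue
        best = min(len(p) for p in simple) - 1
        dist[(s, t)] = best
        paths[(s, t)] = [p for p in simple if len(p) - 1 == best]
    return dist, paths


def oracle_metrics(net: MolecularNetwork):
    """Betweenness, closeness and stress straight from path enumeration."""
    g = net.graph
    dist, paths = enumerate_shortest_paths(net)
    comp_of = {}
    comps = list(nx.connected_components(g))
    for comp in comps:
        for n in comp:
            comp_of[n] = comp
    bet = {n: 0.0 for n in g}
    stress = {n: 0 for n in g}
    for (s, t), plist in paths.items():
        sigma = len(plist)
        for n in g:
            if n in (s, t):
                continue
            through = sum(1 for p in plist if n in p)
            bet[n] += through / sigma
            stress[n] += through
    for n in g:
        size = len(comp_of[n])
        denom = (size - 1) * (size - 2) / 2
        bet[n] = bet[n] / denom if denom > 0 else 0.0
    close = {}
    for n in g:
        ds = [d for (s, t), d in dist.items() if n in (s, t)]
        close[n] = len(ds) / sum(ds) if ds else 0.0
    return {"betweenness": bet, "closeness": close, "stress": stress, "dist": dist,
            "sigma": {pair: len(pl) for pair, pl in paths.items()}}


@pytest.fixture(scope="session")
def afirnet_like_net():
    from afirnet.synthetic import generate_afirnet_like

    return generate_afirnet_like(seed=1)
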
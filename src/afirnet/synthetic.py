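"""Synthetic network generators emulating the curated network's structure.

Three families:

* :func:`generate_ba` — textbook Barabási–Albert preferential attachment,
  the reference model the scale-free classifier must accept;
* :func:`generate_afirnet_like` — a 145-node network matching the global
  statistics of the curated AGE/fertility/immunity network (single
  component, ~260 interaction records including a duplicate and a
  self-loop, mean degree ~3.6, a decaying degree distribution, and exactly
  one hub) with three labeled compartments;
* :func:`fixture` — tiny named graphs (paths, stars, cliques, a cycle)
  bundled with their closed-form metric values, for exact unit testing.

Every generator is deterministic in its seed: the same spec and seed give a
byte-identical edge-record list.
"""

from __future__ import annotations

import random

import networkx as nx
import numpy as np

from .netio import COMPARTMENTS, InteractionRecord, MolecularNetwork
from .scalefree import DegreeDistribution

_INTERACTION_TYPES = ("binds", "activates", "inhibits", "converts_to")

#: engineered degree sequence of the emulated network: one hub of degree 30
#: plus a decaying tail capped at 6.  The cap keeps every ordinary node
#: strictly below mu + sigma (= 6.35 for this sequence) so hub detection
#: finds exactly the designated hub, while the hub point keeps the log-log
#: degree fit steep enough for the scale-free verdict.
_HUB_DEGREE = 30
_TAIL_COUNTS = {1: 26, 2: 26, 3: 26, 4: 22, 5: 22, 6: 22}
_COMPARTMENT_SIZES = {"glycemic_control": 55, "fertility": 50, "immunity": 40}
#: analogue identifiers for the designated hub and the bridge molecules
_HUB_NAME = "TRPV1"
_BRIDGE_NAMES = ("AGE", "RAGE", "CML")


def _to_network(g: nx.Graph, rng: random.Random | None = None) -> MolecularNetwork:
    records = [
        InteractionRecord(str(u), str(v), _INTERACTION_TYPES[i % len(_INTERACTION_TYPES)])
        for i, (u, v) in enumerate(g.edges())
    ]
    return MolecularNetwork(records)


def generate_ba(n: int, m: int, seed: int) -> MolecularNetwork:
    """Barabási–Albert preferential-attachment network.

    Growth starts from an m-node clique; each arriving node attaches to m
    existing nodes with probability proportional to degree (the very first
    attachments are therefore uniform over the clique).  ``m=1`` yields a
    tree with n-1 edges.
    """
    if m < 1 or n <= m:
        raise ValueError("need n > m >= 1")
    # preferential attachment needs at least one edge to start from, so the
    # m=1 case grows from a single edge (the 2-clique) instead
    g0 = nx.complete_graph(max(m, 2))
    g = nx.barabasi_albert_graph(n, m, seed=seed, initial_graph=g0)
    return _to_network(g)


def _connect_components(g: nx.Graph, rng: random.Random) -> None:
    """Degree-preserving rewiring until the graph is connected."""
    comps = sorted((sorted(c) for c in nx.connected_components(g)), key=len, reverse=True)
    while len(comps) > 1:
        big, small = comps[0], comps[1]
        # pick one edge inside each component and cross them over
        e1 = next((u, v) for u, v in g.edges(big) if u in big and v in big)
        e2 = next((u, v) for u, v in g.edges(small) if u in small and v in small)
        g.remove_edge(*e1)
        g.remove_edge(*e2)
        g.add_edge(e1[0], e2[0])
        g.add_edge(e1[1], e2[1])
        comps = sorted((sorted(c) for c in nx.connected_components(g)), key=len, reverse=True)


def generate_afirnet_like(seed: int = 0) -> MolecularNetwork:
    """A 145-node analogue of the curated network.

    The exact engineered degree sequence (hub degree 30, tail capped at 6)
    is realized by Havel–Hakimi construction, patched to a single component
    by degree-preserving edge crossings, then randomized with seeded
    connected double-edge swaps.  258 simple edges plus one duplicate record
    and one self-loop record give 260 interaction records.  Nodes carry
    compartment labels (55 glycemic control, 50 fertility, 40 immunity);
    the designated hub analogue sits in the fertility compartment and the
    bridge analogues (AGE receptors / the best-studied AGE) in glycemic
    control.
    """
    rng = random.Random(seed)
    seq = [_HUB_DEGREE] + [k for k, c in sorted(_TAIL_COUNTS.items(), reverse=True) for _ in range(c)]
    g = nx.havel_hakimi_graph(seq)
    _connect_components(g, rng)
    nx.connected_double_edge_swap(g, nswap=600, seed=rng)

    # name nodes: highest-degree node is the hub, next three are bridges,
    # the rest fill the compartments in a seed-shuffled order
    by_degree = sorted(g.nodes, key=lambda v: (-g.degree[v], v))
    rest = by_degree[4:]
    rng.shuffle(rest)
    mapping = {by_degree[0]: _HUB_NAME}
    for old, new in zip(by_degree[1:4], _BRIDGE_NAMES):
        mapping[old] = new
    labels = {_HUB_NAME: "fertility"}
    labels.update({b: "glycemic_control" for b in _BRIDGE_NAMES})
    remaining = {
        "glycemic_control": _COMPARTMENT_SIZES["glycemic_control"] - len(_BRIDGE_NAMES),
        "fertility": _COMPARTMENT_SIZES["fertility"] - 1,
        "immunity": _COMPARTMENT_SIZES["immunity"],
    }
    prefixes = {"glycemic_control": "GC", "fertility": "FR", "immunity": "IM"}
    counters = dict.fromkeys(COMPARTMENTS, 0)
    it = iter(rest)
    for comp in COMPARTMENTS:
        for _ in range(remaining[comp]):
            old = next(it)
            counters[comp] += 1
            name = f"{prefixes[comp]}-{counters[comp]:03d}"
            mapping[old] = name
            labels[name] = comp
    g = nx.relabel_nodes(g, mapping)

    edges = [(str(u), str(v)) for u, v in g.edges()]
    rng.shuffle(edges)
    records = [
        InteractionRecord(u, v, _INTERACTION_TYPES[i % len(_INTERACTION_TYPES)])
        for i, (u, v) in enumerate(edges)
    ]
    dup = rng.choice(records[: len(records) // 2])
    records.append(InteractionRecord(dup.source, dup.target, dup.interaction_type))
    loop_node = rng.choice(sorted(n for n in g.nodes if g.degree[n] == 3))
    records.append(InteractionRecord(loop_node, loop_node, "self_modifies"))
    return MolecularNetwork(records, compartments=labels)


def exact_powerlaw_distribution(a: float, gamma: float, ks) -> DegreeDistribution:
    """N(k) = a * k**gamma evaluated on the given degrees."""
    ks = np.asarray(sorted(ks), dtype=float)
    return DegreeDistribution(ks, a * ks**gamma)


# ---------------------------------------------------------------------------
# closed-form fixtures
# ---------------------------------------------------------------------------

def _path(n):
    return [(f"n{i}", f"n{i + 1}") for i in range(n - 1)]


def _star(n):  # center n0 with n-1 leaves
    return [("n0", f"n{i}") for i in range(1, n)]


def _clique(n):
    return [(f"n{i}", f"n{j}") for i in range(n) for j in range(i + 1, n)]


_FIXTURES: dict[str, tuple[list, dict]] = {
    "P3": (
        _path(3),
        {
            "num_nodes": 3, "num_edges": 2, "diameter": 2,
            "characteristic_path_length": 4.0 / 3.0,
            "betweenness": {"n0": 0.0, "n1": 1.0, "n2": 0.0},
            "stress": {"n0": 0, "n1": 1, "n2": 0},
            "eccentricity": {"n0": 2, "n1": 1, "n2": 2},
            "radiality": {"n0": 0.75, "n1": 1.0, "n2": 0.75},
            "neighborhood_connectivity": {"n0": 2.0, "n1": 1.0, "n2": 2.0},
            "topological_coefficient": {"n0": 1.0, "n2": 1.0},
            "clustering_coefficient": {"n1": 0.0},
        },
    ),
    "P5": (
        _path(5),
        {
            "num_nodes": 5, "num_edges": 4, "diameter": 4,
            "bottleneck": {"n2": 4, "n0": 0, "n4": 0},
        },
    ),
    "S4": (
        _star(4),
        {
            "num_nodes": 4, "num_edges": 3,
            "betweenness": {"n0": 1.0, "n1": 0.0, "n2": 0.0, "n3": 0.0},
            "closeness": {"n0": 1.0, "n1": 0.6},
            "stress": {"n0": 3},
            "topological_coefficient": {"n1": 1.0},
        },
    ),
    "S5": (
        _star(5),
        {
            "num_nodes": 5, "num_edges": 4,
            "hub_mu": 1.6, "hub_sigma_sample": 1.3416407864998738,
            "hubs": ["n0"],
        },
    ),
    "K3": (
        _clique(3),
        {
            "num_nodes": 3, "num_edges": 3, "diameter": 1,
            "characteristic_path_length": 1.0,
            "clustering_coefficient": {"n0": 1.0, "n1": 1.0, "n2": 1.0},
            "eccentricity": {"n0": 1}, "radiality": {"n0": 1.0},
            "topological_coefficient": {"n0": 1.0},
            "avg_neighbors": 2.0,
        },
    ),
    "K4": (
        _clique(4),
        {"num_nodes": 4, "num_edges": 6, "hubs": []},
    ),
    "C4": (
        [("n0", "n1"), ("n1", "n2"), ("n2", "n3"), ("n3", "n0")],
        {
            "num_nodes": 4, "num_edges": 4,
            "betweenness": {n: 1.0 / 6.0 for n in ("n0", "n1", "n2", "n3")},
            "sigma_opposite": 2, "dist_opposite": 2,
        },
    ),
    # two stars (centers c0, c1) joined by a bridge edge between the centers
    "two_star": (
        [("c0", "a1"), ("c0", "a2"), ("c0", "a3"),
         ("c1", "b1"), ("c1", "b2"), ("c1", "b3"), ("c0", "c1")],
        {
            "num_nodes": 8, "num_edges": 7, "diameter": 3,
            "stress": {"a1": 0, "c0": 15},
        },
    ),
}


def fixture(name: str) -> tuple[MolecularNetwork, dict]:
    """A named closed-form graph plus its exact expected metric values."""
    try:
        edges, expected = _FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; have {sorted(_FIXTURES)}") from None
    records = [InteractionRecord(u, v, "interacts") for u, v in edges]
    return MolecularNetwork(records), dict(expected)


def fixture_names() -> list[str]:
    return sorted(_FIXTURES)
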
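"""Feedforward-module extraction and topology metrics.

Coherent feedforward loops (FFLs) centred on the target gene come in four
types: in types I and IV the direct and indirect paths both activate the
target; in types II and III both repress it.  The **activation module** (AM)
is the union of all overlapping type I/IV FFLs focused on the target, the
**repression module** (RM) the union of types II/III.

Extraction works on the self-loop-free network under the tripartite
partition P1 = direct repressors of the target, P2 = direct activators,
P3 = {target}.  For the AM, four edge sets are united:

    E1: positive edges within P2          (activator -> activator)
    E2: P2 -> target edges (all positive)
    E3: negative edges from P2 to P1      (activator -| repressor)
    E4: P1 -> target edges (all negative)

and the RM is the mirror image (positive edges within P1; P1 -> target;
negative P1 -> P2; P2 -> target).  Iterative deletion of nodes with total
degree < 2 then leaves exactly the overlapping system of complete triads,
since every surviving regulator still reaches the target directly.

Metrics: directed geodesic betweenness normalised by (n-1)(n-2) with
fractional credit over tied geodesics; network diameter as the longest
finite directed shortest path; optional raw max-flow (Freeman) betweenness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import networkx as nx

from .netcore import SignedNetwork

__all__ = [
    "ModulePartition",
    "SubnetworkModule",
    "partition_by_target",
    "extract_module",
    "edge_ratio",
    "centrality",
    "diameter",
    "flow_betweenness",
    "UNDEFINED_RATIO",
]

ModuleKind = Literal["AM", "RM"]

#: sentinel for an edge ratio whose denominator module has no edges
UNDEFINED_RATIO = float("nan")


@dataclass(frozen=True)
class ModulePartition:
    """Tripartite split of nodes by their direct signed edge to the target."""

    P1: frozenset[str]  # repressors of the target
    P2: frozenset[str]  # activators of the target
    P3: frozenset[str]  # the target itself


def partition_by_target(network: SignedNetwork, target: str | None = None) -> ModulePartition:
    """Partition all nodes by the sign of their direct edge to the target.

    Every non-target node must carry a direct signed edge to the target.
    """
    target = target or network.target
    p1, p2, missing = set(), set(), []
    for node in network.node_names:
        if node == target:
            continue
        sign = network.sign(node, target)
        if sign == -1:
            p1.add(node)
        elif sign == 1:
            p2.add(node)
        else:
            missing.append(node)
    if missing:
        raise ValueError(
            f"cannot partition: nodes without a direct edge to {target}: {missing}"
        )
    return ModulePartition(frozenset(p1), frozenset(p2), frozenset({target}))


@dataclass(frozen=True)
class SubnetworkModule:
    """An extracted AM or RM with its topology metrics."""

    kind: ModuleKind
    network: SignedNetwork
    n_nodes: int
    n_edges: int
    n_activating: int
    n_inhibiting: int
    diameter: int
    betweenness: dict[str, float]
    flow_betweenness: dict[str, float] | None = None


def _module_graph(module_net: SignedNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(module_net.node_names)
    for it in module_net.interactions:
        g.add_edge(it.source, it.target, weight=it.sign)
    return g


def extract_module(
    network: SignedNetwork,
    target: str | None = None,
    kind: ModuleKind = "AM",
    with_flow: bool = False,
) -> SubnetworkModule:
    """Extract the activation or repression module around the target.

    Self-loops are removed first, the four edge sets are united, and nodes
    of total (in + out) degree below 2 are deleted iteratively with their
    edges until the reduction reaches its fixed point.  The reduction is
    confluent: the surviving module does not depend on deletion order.
    """
    target = target or network.target
    part = partition_by_target(network, target)
    inner, outer = (part.P2, part.P1) if kind == "AM" else (part.P1, part.P2)

    g = nx.DiGraph()
    for it in network.interactions:
        s, t, w = it.source, it.target, it.sign
        if s == t:
            continue  # loops removed before partitioning
        if t == target:
            g.add_edge(s, t, weight=w)  # E2 (inner, +) and E4 (outer, -)
        elif s in inner and t in inner and w == 1:
            g.add_edge(s, t, weight=w)  # E1
        elif s in inner and t in outer and w == -1:
            g.add_edge(s, t, weight=w)  # E3

    while True:
        prune = [n for n in g if g.in_degree(n) + g.out_degree(n) < 2]
        if not prune:
            break
        g.remove_nodes_from(prune)

    # preserve the parent's node ordering in the reduced module
    kept = [n for n in network.node_names if n in g]
    edges = [(s, t, d["weight"]) for s, t, d in g.edges(data=True)]
    module_net = SignedNetwork(kept, edges, target=target) if target in g else (
        SignedNetwork(kept, edges, target=kept[0]) if kept else None
    )

    if module_net is None:
        return SubnetworkModule(
            kind=kind, network=SignedNetwork([target], [], target=target),
            n_nodes=0, n_edges=0, n_activating=0, n_inhibiting=0,
            diameter=0, betweenness={}, flow_betweenness={} if with_flow else None,
        )

    n_act = sum(1 for *_, w in edges if w == 1)
    return SubnetworkModule(
        kind=kind,
        network=module_net,
        n_nodes=len(kept),
        n_edges=len(edges),
        n_activating=n_act,
        n_inhibiting=len(edges) - n_act,
        diameter=diameter(module_net),
        betweenness=centrality(module_net),
        flow_betweenness=flow_betweenness(module_net) if with_flow else None,
    )


def edge_ratio(am: SubnetworkModule, rm: SubnetworkModule) -> float:
    """AM/RM edge-count ratio; NaN (undefined) when the RM has no edges."""
    if rm.n_edges == 0:
        return UNDEFINED_RATIO
    return am.n_edges / rm.n_edges


def centrality(module: SignedNetwork | SubnetworkModule) -> dict[str, float]:
    """Directed geodesic betweenness, normalised by (n-1)(n-2).

    Endpoints are excluded and credit over multiple tied geodesics is split
    fractionally (the standard Brandes accounting).
    """
    net = module.network if isinstance(module, SubnetworkModule) else module
    g = _module_graph(net)
    return dict(nx.betweenness_centrality(g, normalized=True))


def diameter(module: SignedNetwork | SubnetworkModule) -> int:
    """Longest finite directed shortest path; unreachable pairs ignored."""
    net = module.network if isinstance(module, SubnetworkModule) else module
    g = _module_graph(net)
    best = 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        if dists:
            best = max(best, max(dists.values()))
    return best


def flow_betweenness(module: SignedNetwork | SubnetworkModule) -> dict[str, float]:
    """Raw Freeman max-flow betweenness on unit capacities (unnormalised).

    For every ordered pair (s, t) the contribution of node n is the drop in
    max-flow value when n is removed.  Reported for comparison only; the
    original tooling's exact convention is not reproduced.
    """
    net = module.network if isinstance(module, SubnetworkModule) else module
    g = _module_graph(net)
    for u, v in g.edges:
        g[u][v]["capacity"] = 1
    nodes = list(g.nodes)
    flow = {n: 0.0 for n in nodes}
    base: dict[tuple[str, str], float] = {}
    for s in nodes:
        for t in nodes:
            if s != t:
                base[(s, t)] = nx.maximum_flow_value(g, s, t)
    for n in nodes:
        h = g.copy()
        h.remove_node(n)
        for s in nodes:
            for t in nodes:
                if n in (s, t) or s == t or base[(s, t)] == 0:
                    continue
                flow[n] += base[(s, t)] - nx.maximum_flow_value(h, s, t)
    return flow
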
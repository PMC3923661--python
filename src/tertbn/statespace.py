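"""Exhaustive statespace analysis: basins, attractors, target classification.

The synchronous update induces a functional graph on all 2^N system states
(every state has exactly one successor).  Its weakly connected components
are the basins of attraction; each contains exactly one attractor cycle
(period-1 cycles are steady states).  Because the graph is functional, the
weak component of a state coincides with the set of states sharing its
attractor, so basins are computed by attractor assignment rather than by
building an undirected copy.

Cycles are found by pointer doubling (squaring the successor map N+1 times
maps every state into its own cycle), which is equivalent to iteratively
pruning never-reached leaves until only the input-degree core -- the cycles
-- remains.  Transient lengths (steps until first entry into the cycle) come
from a reverse breadth-first search over predecessor lists.

An attractor is classified for the designated target gene as ``stable_on``
if the target bit is 1 in every cycle state, ``stable_off`` if 0 in every
cycle state, and ``oscillating`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .netcore import RuleSet, SignedNetwork

__all__ = [
    "Attractor",
    "Basin",
    "StateSpace",
    "TargetSummary",
    "successor_array",
    "enumerate_statespace",
    "summarize_target",
    "export_statespace_graph",
    "MAX_NODES",
]

#: default enumeration bound; 2^24 successors is the largest array kept in RAM
MAX_NODES = 24

TargetClass = Literal["stable_on", "stable_off", "oscillating"]


@dataclass(frozen=True)
class Attractor:
    """An attractor cycle with its target-gene classification."""

    cycle: tuple[int, ...]
    target_class: TargetClass

    @property
    def period(self) -> int:
        return len(self.cycle)

    @property
    def is_fixed_point(self) -> bool:
        return len(self.cycle) == 1


@dataclass(frozen=True)
class Basin:
    """A basin of attraction (weak component of the functional graph)."""

    attractor: Attractor
    member_states: np.ndarray  # sorted state encodings
    longest_transient: int

    @property
    def size(self) -> int:
        return int(self.member_states.size)


@dataclass(frozen=True)
class StateSpace:
    """Successor map over all 2^N states plus its basin decomposition.

    Basins are ordered by decreasing size (ties broken by smallest cycle
    state), so ``basins[0]`` is the dominant basin; "steady state 1" of a
    two-fixed-point model is ``basins[0].attractor.cycle[0]``.
    """

    network: SignedNetwork
    rules: RuleSet
    successor: np.ndarray
    basins: tuple[Basin, ...]
    _basin_index: np.ndarray  # state -> position in ``basins``

    @property
    def n_states(self) -> int:
        return int(self.successor.size)

    @property
    def attractors(self) -> tuple[Attractor, ...]:
        return tuple(b.attractor for b in self.basins)

    def basin_of(self, state: int) -> Basin:
        return self.basins[int(self._basin_index[state])]

    def stable_on_fraction(self) -> float:
        on = sum(b.size for b in self.basins if b.attractor.target_class == "stable_on")
        return on / self.n_states


def _target_class(cycle: Sequence[int], target_bit: int) -> TargetClass:
    on = [bool(s & target_bit) for s in cycle]
    if all(on):
        return "stable_on"
    if not any(on):
        return "stable_off"
    return "oscillating"


def successor_array(
    network: SignedNetwork,
    rules: RuleSet | None = None,
    max_nodes: int = MAX_NODES,
    chunk: int = 1 << 16,
) -> np.ndarray:
    """Successor of every state in [0, 2^N), by direct threshold evaluation.

    Vectorised over states and chunked to bound memory; identical to mapping
    :func:`tertbn.dynamics.next_state` over the whole statespace.
    """
    rules = rules or RuleSet.basal()
    rules.validate_for(network)
    n = network.n_nodes
    if n > max_nodes:
        raise ValueError(
            f"{n}-node network exceeds the {max_nodes}-node enumeration bound; "
            "reduce the network or raise max_nodes explicitly"
        )
    W = network.weight_matrix()
    phi = rules.phi_vector(network)
    on_idx = [network.index(g) for g in rules.forced_on]
    off_idx = [network.index(g) for g in rules.forced_off]
    m = 1 << n
    shifts = np.arange(n, dtype=np.uint32)
    succ = np.empty(m, dtype=np.int64)
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        states = np.arange(lo, hi, dtype=np.uint32)
        bits = ((states[:, None] >> shifts) & 1).astype(np.int8)
        nxt = (bits @ W >= phi).astype(np.uint32)
        if on_idx:
            nxt[:, on_idx] = 1
        if off_idx:
            nxt[:, off_idx] = 0
        succ[lo:hi] = (nxt << shifts).sum(axis=1).astype(np.int64)
    return succ


def _find_cycles(succ: np.ndarray, n: int) -> tuple[list[list[int]], np.ndarray]:
    """All cycles of the functional graph and the per-state cycle index."""
    h = succ.copy()
    for _ in range(n + 1):  # f^(2^(n+1)) lands in the cycle from any state
        h = h[h]
    cycle_id = np.full(succ.size, -1, dtype=np.int32)
    cycles: list[list[int]] = []
    for rep in np.unique(h):
        rep = int(rep)
        if cycle_id[rep] >= 0:
            continue
        cyc = [rep]
        s = int(succ[rep])
        while s != rep:
            cyc.append(s)
            s = int(succ[s])
        # canonical orientation: start at the smallest state of the cycle
        k = cyc.index(min(cyc))
        cyc = cyc[k:] + cyc[:k]
        cid = len(cycles)
        cycles.append(cyc)
        for c in cyc:
            cycle_id[c] = cid
    basin_of = cycle_id[h]
    return cycles, basin_of


def _transient_distances(succ: np.ndarray, cycle_states: np.ndarray) -> np.ndarray:
    """Steps from each state to its first cycle state (reverse BFS)."""
    m = succ.size
    order = np.argsort(succ, kind="stable")
    succ_sorted = succ[order]
    starts = np.searchsorted(succ_sorted, np.arange(m + 1))
    dist = np.full(m, -1, dtype=np.int64)
    dist[cycle_states] = 0
    frontier = cycle_states
    d = 0
    while frontier.size:
        d += 1
        preds = np.concatenate(
            [order[starts[v]: starts[v + 1]] for v in frontier]
        ) if frontier.size else np.empty(0, dtype=np.int64)
        preds = preds[dist[preds] < 0]
        dist[preds] = d
        frontier = preds
    return dist


def enumerate_statespace(
    network: SignedNetwork,
    rules: RuleSet | None = None,
    max_nodes: int = MAX_NODES,
    transients: bool = True,
) -> StateSpace:
    """Enumerate all 2^N transitions and decompose the statespace into basins.

    With ``transients=False`` the per-basin longest transient is skipped
    (reported as -1) -- the fast path for ensemble screening where only
    attractor counts and basin sizes matter.
    """
    rules = rules or RuleSet.basal()
    succ = successor_array(network, rules, max_nodes=max_nodes)
    n = network.n_nodes
    cycles, basin_idx = _find_cycles(succ, n)
    target_bit = 1 << network.index(network.target)

    all_cycle_states = np.fromiter(
        (s for cyc in cycles for s in cyc), dtype=np.int64
    )
    dist = (
        _transient_distances(succ, all_cycle_states)
        if transients
        else None
    )

    order = np.argsort(basin_idx, kind="stable")
    sizes = np.bincount(basin_idx, minlength=len(cycles))
    bounds = np.concatenate([[0], np.cumsum(sizes)])

    basins = []
    for cid, cyc in enumerate(cycles):
        members = np.sort(order[bounds[cid]: bounds[cid + 1]])
        longest = int(dist[members].max()) if dist is not None else -1
        basins.append(
            Basin(
                attractor=Attractor(tuple(cyc), _target_class(cyc, target_bit)),
                member_states=members,
                longest_transient=longest,
            )
        )
    # dominant basin first; deterministic tie-break on smallest cycle state
    perm = sorted(range(len(basins)),
                  key=lambda i: (-basins[i].size, basins[i].attractor.cycle[0]))
    rank = {cid: r for r, cid in enumerate(perm)}
    basin_index = np.vectorize(rank.__getitem__, otypes=[np.int32])(basin_idx)
    return StateSpace(
        network=network,
        rules=rules,
        successor=succ,
        basins=tuple(basins[i] for i in perm),
        _basin_index=basin_index,
    )


@dataclass(frozen=True)
class TargetSummary:
    """Per-attractor summary plus the aggregate stable-on fraction."""

    table: pd.DataFrame
    stable_on_fraction: float


def summarize_target(space: StateSpace, target: str | None = None) -> TargetSummary:
    """Tabulate each attractor's class, basin size/fraction and transient.

    The aggregate ``stable_on_fraction`` is the proportion of all system
    states whose trajectories end in an attractor with the target stably on
    -- the quantity plotted in perturbation scans.
    """
    target = target or space.network.target
    if target not in space.network:
        raise ValueError(f"unknown target gene {target!r}")
    tb = 1 << space.network.index(target)
    m = space.n_states
    rows = []
    stable_on = 0
    for i, b in enumerate(space.basins, start=1):
        cls = _target_class(b.attractor.cycle, tb)
        if cls == "stable_on":
            stable_on += b.size
        rows.append(
            {
                "attractor_id": i,
                "period": b.attractor.period,
                "target_class": cls,
                "basin_size": b.size,
                "basin_fraction": b.size / m,
                "longest_transient": b.longest_transient,
            }
        )
    return TargetSummary(table=pd.DataFrame(rows), stable_on_fraction=stable_on / m)


def export_statespace_graph(
    space: StateSpace, path, prune_leaves: bool = False
) -> None:
    """Write the functional graph as Pajek .net plus a .clu partition file.

    Every state has one outgoing arc (to its successor).  With
    ``prune_leaves`` the vertex set is restricted to states with at least one
    predecessor, exposing the core statespace structure; arcs are kept when
    both endpoints survive.  The partition marks attractor states 1 and
    transient states 0.
    """
    from . import io

    succ = space.successor
    cycle_states = {s for b in space.basins for s in b.attractor.cycle}
    if prune_leaves:
        indeg = np.bincount(succ, minlength=succ.size)
        keep = np.flatnonzero(indeg > 0)
    else:
        keep = np.arange(succ.size)
    keep_set = set(int(s) for s in keep)
    arcs = [
        (int(s), int(succ[s]))
        for s in keep
        if int(succ[s]) in keep_set
    ]
    partition = [1 if int(s) in cycle_states else 0 for s in keep]
    io.write_pajek_graph(
        labels=[str(int(s)) for s in keep],
        arcs=[(int(s), int(t), 1) for s, t in arcs],
        ids=[int(s) for s in keep],
        path=path,
        partition=partition,
    )
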
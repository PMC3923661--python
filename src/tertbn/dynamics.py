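"""Synchronous activation-dominant threshold dynamics.

Every node j holds a binary state sigma_j.  At each step all free nodes are
updated simultaneously from the same input state:

    sigma_j(t+1) = 1  iff  sum_i  w_ij * sigma_i(t)  >=  phi_j      (phi_j = 0)

where w_ij is +1 for an activating and -1 for a repressive input.  The tie
(sum equal to the threshold) resolves to ON, so a node is switched off only
when strictly more of its active inputs are repressive than activating --
the rule is activation-dominant, and an input-free node is constitutively on.
Forced nodes ignore their inputs and take their forced value, but still feed
downstream sums with their current state.

States are encoded as integers: bit i (least significant = node index 0)
carries the state of node i, so a network of N nodes has statespace
[0, 2^N).  Because the update is a deterministic function on a finite set,
every trajectory enters a cycle within at most 2^N + 1 steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netcore import RuleSet, SignedNetwork

__all__ = [
    "Trajectory",
    "encode_state",
    "decode_state",
    "next_state",
    "run_to_attractor",
]


def encode_state(bits, network: SignedNetwork | None = None) -> int:
    """Encode an iterable of per-node 0/1 values (index order) as an integer."""
    enc = 0
    for i, b in enumerate(bits):
        if b not in (0, 1, False, True):
            raise ValueError(f"node state must be 0/1, got {b!r}")
        if b:
            enc |= 1 << i
    return enc


def decode_state(state: int, n_nodes: int) -> tuple[int, ...]:
    """Per-node 0/1 tuple (index order) for an encoded state."""
    _check_state(state, n_nodes)
    return tuple((state >> i) & 1 for i in range(n_nodes))


def _check_state(state: int, n_nodes: int) -> None:
    if not 0 <= state < (1 << n_nodes):
        raise ValueError(
            f"state {state} out of range for a {n_nodes}-node network"
        )


def next_state(network: SignedNetwork, rules: RuleSet, state: int) -> int:
    """One synchronous update of *state* under the threshold rule."""
    n = network.n_nodes
    _check_state(state, n)
    rules.validate_for(network)
    W = network.weight_matrix()
    bits = np.fromiter(((state >> i) & 1 for i in range(n)), dtype=np.int8, count=n)
    sums = bits @ W
    phi = rules.phi_vector(network)
    nxt = (sums >= phi).astype(np.int64)
    for g in rules.forced_on:
        nxt[network.index(g)] = 1
    for g in rules.forced_off:
        nxt[network.index(g)] = 0
    return int((nxt << np.arange(n)).sum())


@dataclass(frozen=True)
class Trajectory:
    """A trajectory iterated to its attractor.

    ``path`` lists the visited states from the initial state up to and
    including the full attractor cycle (each state once, in first-visit
    order); ``transient_length`` counts the update steps before the first
    attractor state; ``attractor`` is the cycle in first-visit order.
    """

    path: tuple[int, ...]
    transient_length: int
    attractor: tuple[int, ...]

    @property
    def period(self) -> int:
        return len(self.attractor)


def run_to_attractor(
    network: SignedNetwork, rules: RuleSet, initial: int
) -> Trajectory:
    """Iterate ``next_state`` from *initial* until a state repeats.

    Deterministic; terminates within 2^N + 1 steps.  The returned cycle is
    ordered from the first revisited state onward.
    """
    _check_state(initial, network.n_nodes)
    seen: dict[int, int] = {}
    path: list[int] = []
    s = initial
    while s not in seen:
        seen[s] = len(path)
        path.append(s)
        s = next_state(network, rules, s)
    start = seen[s]
    return Trajectory(
        path=tuple(path),
        transient_length=start,
        attractor=tuple(path[start:]),
    )
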
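"""Random edge attacks and semi-random network ensembles.

Two ensemble protocols relate the dominance of the activation module to the
multiplicity of target-on attractors:

* **Attack series** -- the wild-type model is re-wired by deleting AM (or
  AM and RM) edges independently with a deletion probability swept from
  0.1 to 0.7 in 0.05 increments.  Edges connecting directly to the target
  are never attacked, so the activator/repressor partition is preserved.
  For every attacked network the modules are re-extracted, the edge ratio
  recorded, and the statespace enumerated to count stable target-on
  attractors.
* **Semi-random networks** -- node panels with one fully downstream
  regulated node (every other node carries a mandatory signed edge to it)
  and Bernoulli edge seeding among the regulators, spanning a range of
  densities.

Edge-ratio populations grouped by on-state multiplicity {0, 1, 2, >=3} are
compared by the Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import isnan
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .motifs import extract_module
from .netcore import RuleSet, SignedNetwork
from .statespace import enumerate_statespace

__all__ = [
    "AttackSpec",
    "EnsembleRecord",
    "attack_series",
    "random_network",
    "random_network_series",
    "multiplicity_stats",
]

AttackMode = Literal["AM_only", "AM_and_RM"]

DEFAULT_PROBABILITIES = tuple(np.round(np.arange(0.10, 0.7001, 0.05), 2))


@dataclass(frozen=True)
class AttackSpec:
    """Configuration of a random edge-attack series.

    Defaults give 13 probabilities x 2 modes x 23 replicates = 598 networks,
    topped up to 600 with one extra replicate per mode at the lowest
    probability.
    """

    probabilities: tuple[float, ...] = DEFAULT_PROBABILITIES
    modes: tuple[AttackMode, ...] = ("AM_only", "AM_and_RM")
    replicates_per_cell: int = 23
    extra_replicates_at_first: int = 1
    seed: int = 0
    protect_target_edges: bool = True

    def __post_init__(self) -> None:
        if not all(0 < p < 1 for p in self.probabilities):
            raise ValueError("attack probabilities must lie in (0, 1)")
        bad = [m for m in self.modes if m not in ("AM_only", "AM_and_RM")]
        if bad:
            raise ValueError(f"unknown attack modes: {bad}")

    @property
    def total_networks(self) -> int:
        return len(self.modes) * (
            len(self.probabilities) * self.replicates_per_cell
            + self.extra_replicates_at_first
        )


@dataclass(frozen=True)
class EnsembleRecord:
    """Per-network outcome of an attack or random-ensemble run."""

    network_id: int
    mode: str
    deletion_p: float
    am_edges: int
    rm_edges: int
    edge_ratio: float  # NaN when the RM has no edges
    n_stable_on: int
    seed: int


def _child_seed(master: int, index: int) -> int:
    return int(np.random.SeedSequence([master, index]).generate_state(1)[0] % (1 << 31))


def _count_stable_on(network: SignedNetwork) -> int:
    space = enumerate_statespace(network, RuleSet.basal(), transients=False)
    return sum(
        1 for b in space.basins if b.attractor.target_class == "stable_on"
    )


def _measure(network: SignedNetwork, network_id: int, mode: str,
             deletion_p: float, seed: int) -> EnsembleRecord:
    am = extract_module(network, kind="AM")
    rm = extract_module(network, kind="RM")
    ratio = am.n_edges / rm.n_edges if rm.n_edges else float("nan")
    return EnsembleRecord(
        network_id=network_id,
        mode=mode,
        deletion_p=deletion_p,
        am_edges=am.n_edges,
        rm_edges=rm.n_edges,
        edge_ratio=ratio,
        n_stable_on=_count_stable_on(network),
        seed=seed,
    )


def attack_series(network: SignedNetwork, spec: AttackSpec) -> list[EnsembleRecord]:
    """Run the full random-attack series; bit-reproducible from spec.seed.

    The attackable pool is the edge set of the extracted AM (plus RM for the
    ``AM_and_RM`` mode) minus all target-incident edges; each pool edge is
    deleted independently with the cell's probability, and the resulting
    network is measured (module edge counts, edge ratio, stable-on count).
    """
    target = network.target
    am = extract_module(network, kind="AM")
    rm = extract_module(network, kind="RM")
    pools: dict[str, list[tuple[str, str]]] = {}
    am_pool = [
        (it.source, it.target)
        for it in am.network.interactions
        if not (spec.protect_target_edges and it.target == target)
    ]
    rm_pool = [
        (it.source, it.target)
        for it in rm.network.interactions
        if not (spec.protect_target_edges and it.target == target)
    ]
    pools["AM_only"] = sorted(set(am_pool))
    pools["AM_and_RM"] = sorted(set(am_pool) | set(rm_pool))

    records = []
    idx = 0
    for mode in spec.modes:
        pool = pools[mode]
        for j, p in enumerate(spec.probabilities):
            reps = spec.replicates_per_cell + (
                spec.extra_replicates_at_first if j == 0 else 0
            )
            for _ in range(reps):
                child = _child_seed(spec.seed, idx)
                rng = np.random.default_rng(child)
                drop = [e for e in pool if rng.random() < p]
                attacked = network.with_edges_removed(drop)
                records.append(_measure(attacked, idx, mode, float(p), child))
                idx += 1
    return records


def random_network(
    n: int, edge_p: float, sign_p: float = 0.5, seed: int = 0
) -> SignedNetwork:
    """Semi-random signed network with one fully downstream regulated node.

    Nodes ``N1..N{n-1}`` each carry a mandatory signed edge to the regulated
    node ``TARGET`` (sign +1 with probability ``sign_p``), which has
    out-degree 0.  Every ordered regulator pair, self-loops included, gains
    an edge with probability ``edge_p`` and an independent Bernoulli sign.
    """
    if n < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng(seed)
    regulators = [f"N{i}" for i in range(1, n)]
    nodes = regulators + ["TARGET"]
    edges: list[tuple[str, str, int]] = []
    for g in regulators:
        edges.append((g, "TARGET", 1 if rng.random() < sign_p else -1))
    for s in regulators:
        for t in regulators:
            if rng.random() < edge_p:
                edges.append((s, t, 1 if rng.random() < sign_p else -1))
    return SignedNetwork(nodes, edges, target="TARGET")


def random_network_series(
    densities: Sequence[float] = (0.10, 0.15, 0.20),
    per_density: int = 100,
    n: int = 15,
    sign_p: float = 0.5,
    seed: int = 0,
) -> list[EnsembleRecord]:
    """Generate and measure a panel of semi-random networks.

    Default panel: 100 networks at each seeding density 0.1 / 0.15 / 0.2,
    15 nodes each.  ``deletion_p`` in the records carries the density.
    """
    records = []
    idx = 0
    for d in densities:
        for _ in range(per_density):
            child = _child_seed(seed, idx)
            net = random_network(n, d, sign_p, seed=child)
            records.append(_measure(net, idx, "random", float(d), child))
            idx += 1
    return records


def multiplicity_stats(records: Iterable[EnsembleRecord]) -> dict:
    """Group edge ratios by on-state multiplicity and test adjacent groups.

    Records are binned by ``n_stable_on`` into {0, 1, 2, >=3}; undefined
    (NaN) edge ratios are excluded from the statistics and counted.  Returns
    group sizes, median edge ratios and Wilcoxon rank-sum p-values for each
    adjacent pair of non-empty groups.
    """
    recs = list(records)
    excluded = sum(1 for r in recs if isnan(r.edge_ratio))
    bins: dict[str, list[float]] = {"0": [], "1": [], "2": [], "3+": []}
    for r in recs:
        if isnan(r.edge_ratio):
            continue
        key = str(r.n_stable_on) if r.n_stable_on < 3 else "3+"
        bins[key].append(r.edge_ratio)
    nonempty = [k for k in ("0", "1", "2", "3+") if bins[k]]
    if len(nonempty) < 2:
        raise ValueError("need at least two non-empty multiplicity groups")
    medians = {k: float(np.median(bins[k])) for k in nonempty}
    sizes = {k: len(bins[k]) for k in nonempty}
    pvals = {}
    for a, b in zip(nonempty[:-1], nonempty[1:]):
        stat = stats.ranksums(bins[a], bins[b])
        pvals[f"{a}_vs_{b}"] = float(stat.pvalue)
    return {
        "group_sizes": sizes,
        "median_edge_ratio": medians,
        "ranksum_p": pvals,
        "excluded_undefined_ratios": excluded,
    }
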
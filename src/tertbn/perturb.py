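"""Rule-table mutation experiments, bit-flip noise and rule-set shifts.

Three protocols probe the stability of the regulated target gene:

* **Perturbation scans** force individual nodes constitutively on or off
  (single scans), optionally on top of an existing forced background
  (double scans), and quantify the fraction of statespace evolving to
  attractors with the target stably on.
* **Bit-flip noise** takes a steady state, transiently flips one node's bit
  and lets the system evolve freely under the *same* ruleset, recording
  whether it returns or switches attractor.  The flip is a state change, not
  a rule change; a flip at a node the ruleset forces is reasserted by the
  override before it can propagate, so it can never cause a switch.
* **Rule-set shifts** take an attractor state of one ruleset and evolve it
  under another (e.g. basal -> inhibitor-modified and back), modelling
  treatment onset and wear-off applied to the different network states.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import pandas as pd

from .dynamics import run_to_attractor
from .netcore import RuleSet, SignedNetwork
from .statespace import Attractor, enumerate_statespace, summarize_target

__all__ = [
    "PerturbationSpec",
    "FlipResult",
    "perturbation_scan",
    "default_direction_specs",
    "co_suppression_specs",
    "bitflip_map",
    "ruleset_shift",
]


@dataclass(frozen=True)
class PerturbationSpec:
    """A set of constitutive overrides to apply on top of a base ruleset."""

    forced: Mapping[str, Literal["forced_on", "forced_off"]]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.forced:
            raise ValueError("perturbation spec must force at least one node")
        bad = [m for m in self.forced.values() if m not in ("forced_on", "forced_off")]
        if bad:
            raise ValueError(f"invalid forced modes: {bad}")

    def as_ruleset(self) -> RuleSet:
        return RuleSet.forcing(
            forced_on=[g for g, m in self.forced.items() if m == "forced_on"],
            forced_off=[g for g, m in self.forced.items() if m == "forced_off"],
            label=self.label,
        )

    def validate(self, network: SignedNetwork, target: str) -> None:
        if target in self.forced:
            raise ValueError(
                f"spec {self.label!r} forces the target gene {target}"
            )
        unknown = [g for g in self.forced if g not in network]
        if unknown:
            raise ValueError(f"spec {self.label!r} forces unknown nodes {unknown}")


def perturbation_scan(
    network: SignedNetwork,
    base_rules: RuleSet,
    specs: Iterable[PerturbationSpec],
    target: str | None = None,
) -> pd.DataFrame:
    """Statespace summary for each spec merged into the base ruleset.

    Returns one row per spec: the stable-on fraction of the target plus the
    number of attractors and a per-attractor detail list of
    ``(target_class, basin_fraction)`` pairs sorted by decreasing basin size.
    An empty spec list yields the base-model summary as a single row.
    """
    target = target or network.target
    rows = []
    spec_list = list(specs)
    if not spec_list:
        spec_list = [None]  # type: ignore[list-item]
    for spec in spec_list:
        if spec is None:
            rules, label = base_rules, base_rules.label or "base"
        else:
            spec.validate(network, target)
            rules = base_rules.merged_with(spec.as_ruleset())
            label = spec.label or "+".join(
                f"{g}:{m.removeprefix('forced_')}" for g, m in spec.forced.items()
            )
        space = enumerate_statespace(network, rules, transients=False)
        summ = summarize_target(space, target)
        detail = [
            (r.target_class, r.basin_fraction)
            for r in summ.table.itertuples(index=False)
        ]
        rows.append(
            {
                "spec_label": label,
                "n_attractors": len(space.basins),
                "stable_on_fraction": summ.stable_on_fraction,
                "attractor_detail": detail,
            }
        )
    return pd.DataFrame(rows)


def default_direction_specs(
    network: SignedNetwork, target: str | None = None
) -> list[PerturbationSpec]:
    """One spec per non-target node: activators forced off, repressors on.

    The single-scan convention: suppress each direct activator of the target
    and constitutively activate each direct repressor, so every perturbation
    pushes against the target individually.
    """
    target = target or network.target
    specs = []
    missing = []
    for node in network.node_names:
        if node == target:
            continue
        sign = network.sign(node, target)
        if sign == 1:
            specs.append(PerturbationSpec({node: "forced_off"}, label=f"{node}-off"))
        elif sign == -1:
            specs.append(PerturbationSpec({node: "forced_on"}, label=f"{node}-on"))
        else:
            missing.append(node)
    if missing:
        raise ValueError(
            f"nodes without a direct edge to {target}: {missing}"
        )
    return specs


def co_suppression_specs(
    network: SignedNetwork, target: str | None = None
) -> list[PerturbationSpec]:
    """One forced-off spec per non-target node (RNAi-style co-suppression).

    Companion to :func:`default_direction_specs` for double scans validated
    with siRNA knockdowns, where every secondary perturbation is a
    suppression regardless of the node's sign at the target.
    """
    target = target or network.target
    return [
        PerturbationSpec({node: "forced_off"}, label=f"{node}-off")
        for node in network.node_names
        if node != target
    ]


@dataclass(frozen=True)
class FlipResult:
    """Outcome of one single-bit noise event at a steady state."""

    flipped_node: str
    origin: int
    destination: Attractor
    switched: bool


def bitflip_map(
    network: SignedNetwork,
    rules: RuleSet,
    steady: int,
    exclude: Iterable[str] | None = None,
) -> list[FlipResult]:
    """Flip each non-excluded node's bit in *steady* and evolve freely.

    ``steady`` must be a fixed point of the ruleset.  The flip is transient
    (not held): the system evolves under the unchanged ruleset, and the
    destination attractor is recorded together with whether it differs from
    the origin.  The target gene is excluded by default.  Forced bits are
    reasserted in the flipped state, so flips at forced nodes never switch.
    """
    exclude_set = set(exclude) if exclude is not None else {network.target}
    traj = run_to_attractor(network, rules, steady)
    if traj.transient_length != 0 or traj.period != 1:
        raise ValueError(
            f"state {steady} is not a fixed point of the given ruleset"
        )
    results = []
    for node in network.node_names:
        if node in exclude_set:
            continue
        flipped = steady ^ (1 << network.index(node))
        # the constitutive override holds at every instant, including t=0
        for g in rules.forced_on:
            flipped |= 1 << network.index(g)
        for g in rules.forced_off:
            flipped &= ~(1 << network.index(g))
        dest = run_to_attractor(network, rules, flipped)
        tb = 1 << network.index(network.target)
        dest_attr = Attractor(
            dest.attractor,
            (
                "stable_on"
                if all(s & tb for s in dest.attractor)
                else "stable_off"
                if not any(s & tb for s in dest.attractor)
                else "oscillating"
            ),
        )
        results.append(
            FlipResult(
                flipped_node=node,
                origin=steady,
                destination=dest_attr,
                switched=steady not in dest.attractor,
            )
        )
    return results


def ruleset_shift(
    network: SignedNetwork, origin_state: int, new_rules: RuleSet
) -> Attractor:
    """Evolve an attractor state of some source ruleset under new rules."""
    traj = run_to_attractor(network, new_rules, origin_state)
    tb = 1 << network.index(network.target)
    cyc = traj.attractor
    cls = (
        "stable_on"
        if all(s & tb for s in cyc)
        else "stable_off"
        if not any(s & tb for s in cyc)
        else "oscillating"
    )
    return Attractor(cyc, cls)
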
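"""Network and rule types for the TERT transcriptional neighbourhood model.

A :class:`SignedNetwork` is a static gene-regulatory topology: an ordered set
of gene nodes and signed directed interactions (weight +1 activating, -1
repressive).  Networks can be built from transfection-screen summary tables
(fold-change / p-value records) under explicit cutoffs, or loaded as the
packaged canonical 15-node TERT model and its 16-node ETS2-extended variant.

The canonical model was assembled from a reporter screen in A2780 ovarian
adenocarcinoma cells: 14 transcription-factor promoters plus the TERT
promoter, each interrogated against the panel of overexpressed factors.  An
interaction enters the model when the promoter responds at least 1.5-fold
(up or down) with p < 0.01; one relaxation retains STAT3 as a TERT activator.
The result is a 15-node, 92-interaction network (50 activating / 42
repressive) in which TERT has 7 direct activators and 7 direct repressors
and no outgoing edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GeneNode",
    "Interaction",
    "SignedNetwork",
    "NodeMode",
    "RuleSet",
    "EdgeCutoffs",
    "SCREEN_COLUMNS",
    "build_network_from_screen",
    "derive_overrides_from_treatment",
    "canonical_tert_network",
    "ets2_extended_network",
    "no_stat3_network",
]

#: canonical column order of a screen-record table
SCREEN_COLUMNS = ("promoter", "perturbation", "fold_change", "p_value")

TertRole = Literal["activator", "repressor", "target", "unclassified"]


@dataclass(frozen=True)
class GeneNode:
    """A gene in the network with its fixed position in the node ordering."""

    name: str
    index: int
    tert_role: TertRole = "unclassified"


@dataclass(frozen=True)
class Interaction:
    """Signed directed interaction ``source -> target`` (sign in {+1, -1})."""

    source: str
    target: str
    sign: int

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ValueError(f"interaction sign must be +1 or -1, got {self.sign}")


class SignedNetwork:
    """Ordered gene nodes plus a set of signed directed interactions.

    Parameters
    ----------
    node_names:
        Gene symbols in fixed order; node *i* maps to bit *i* of a system
        state.  Names must be unique.
    interactions:
        Iterable of :class:`Interaction` (or ``(source, target, sign)``
        tuples).  ``(source, target)`` pairs must be unique; self-loops are
        permitted.  Every endpoint must be a declared node.
    target:
        Symbol of the regulated focus gene (default ``"TERT"``).
    """

    def __init__(
        self,
        node_names: Iterable[str],
        interactions: Iterable[Interaction | tuple],
        target: str = "TERT",
    ) -> None:
        names = list(node_names)
        if len(set(names)) != len(names):
            raise ValueError("node names must be unique")
        self._index = {g: i for i, g in enumerate(names)}
        if target not in self._index:
            raise ValueError(f"target {target!r} is not a declared node")
        self.target = target

        edges: dict[tuple[str, str], int] = {}
        for it in interactions:
            if not isinstance(it, Interaction):
                it = Interaction(*it)
            if it.source not in self._index or it.target not in self._index:
                raise ValueError(
                    f"interaction {it.source}->{it.target} references an undeclared node"
                )
            key = (it.source, it.target)
            if key in edges:
                raise ValueError(f"duplicate interaction for pair {key}")
            edges[key] = it.sign
        self._edges = edges

        self.nodes = tuple(
            GeneNode(g, i, self._role_of(g)) for i, g in enumerate(names)
        )

    # -- basic introspection -------------------------------------------------

    def _role_of(self, gene: str) -> TertRole:
        if gene == self.target:
            return "target"
        sign = self._edges.get((gene, self.target))
        if sign == 1:
            return "activator"
        if sign == -1:
            return "repressor"
        return "unclassified"

    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def interactions(self) -> tuple[Interaction, ...]:
        return tuple(
            Interaction(s, t, w) for (s, t), w in sorted(self._edges.items())
        )

    @property
    def n_interactions(self) -> int:
        return len(self._edges)

    def index(self, gene: str) -> int:
        return self._index[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def sign(self, source: str, target: str) -> int | None:
        """Sign of the edge ``source -> target`` or None if absent."""
        return self._edges.get((source, target))

    def in_degree(self, gene: str) -> int:
        """Number of inputs k_j of node *gene* (the update-rule fan-in)."""
        return sum(1 for (_, t) in self._edges if t == gene)

    def out_degree(self, gene: str) -> int:
        return sum(1 for (s, _) in self._edges if s == gene)

    def activators_of(self, gene: str) -> tuple[str, ...]:
        return tuple(s for (s, t), w in sorted(self._edges.items()) if t == gene and w == 1)

    def repressors_of(self, gene: str) -> tuple[str, ...]:
        return tuple(s for (s, t), w in sorted(self._edges.items()) if t == gene and w == -1)

    def weight_matrix(self) -> np.ndarray:
        """N x N int8 matrix W with W[i, j] the weight of edge i -> j."""
        W = np.zeros((self.n_nodes, self.n_nodes), dtype=np.int8)
        for (s, t), w in self._edges.items():
            W[self._index[s], self._index[t]] = w
        return W

    # -- derived networks ----------------------------------------------------

    def without_edge(self, source: str, target: str) -> "SignedNetwork":
        edges = [it for it in self.interactions if (it.source, it.target) != (source, target)]
        return SignedNetwork(self.node_names, edges, target=self.target)

    def with_edges_removed(self, pairs: Iterable[tuple[str, str]]) -> "SignedNetwork":
        drop = set(pairs)
        edges = [it for it in self.interactions if (it.source, it.target) not in drop]
        return SignedNetwork(self.node_names, edges, target=self.target)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedNetwork):
            return NotImplemented
        return (
            self.node_names == other.node_names
            and self._edges == other._edges
            and self.target == other.target
        )

    def __repr__(self) -> str:
        return (
            f"SignedNetwork({self.n_nodes} nodes, {self.n_interactions} "
            f"interactions, target={self.target!r})"
        )


Mode = Literal["free", "forced_on", "forced_off"]


@dataclass(frozen=True)
class NodeMode:
    """Dynamic mode of one node.

    ``free`` nodes follow the threshold rule with threshold ``phi``;
    ``forced_on``/``forced_off`` nodes ignore their inputs entirely (they
    still feed downstream sums with their current state value).
    """

    mode: Mode = "free"
    phi: float = 0.0


class RuleSet:
    """Per-node dynamic modes; defaults to all-free with phi = 0.

    Models "rule-table mutations": constitutive activation (``forced_on``) or
    suppression (``forced_off``) of individual nodes, as used to simulate
    overexpression, knockdown or inhibitor effects.
    """

    def __init__(self, modes: Mapping[str, NodeMode | str] | None = None,
                 label: str = "") -> None:
        self.label = label
        self._modes: dict[str, NodeMode] = {}
        for gene, m in (modes or {}).items():
            if isinstance(m, str):
                m = NodeMode(mode=m)  # type: ignore[arg-type]
            if m.mode not in ("free", "forced_on", "forced_off"):
                raise ValueError(f"unknown mode {m.mode!r} for {gene}")
            self._modes[gene] = m

    @classmethod
    def basal(cls) -> "RuleSet":
        return cls({}, label="basal")

    @classmethod
    def forcing(cls, forced_on: Iterable[str] = (), forced_off: Iterable[str] = (),
                label: str = "") -> "RuleSet":
        on, off = set(forced_on), set(forced_off)
        clash = on & off
        if clash:
            raise ValueError(f"nodes forced both on and off: {sorted(clash)}")
        modes: dict[str, NodeMode] = {}
        modes.update({g: NodeMode("forced_on") for g in on})
        modes.update({g: NodeMode("forced_off") for g in off})
        return cls(modes, label=label)

    def mode_of(self, gene: str) -> NodeMode:
        return self._modes.get(gene, NodeMode())

    @property
    def forced_on(self) -> frozenset[str]:
        return frozenset(g for g, m in self._modes.items() if m.mode == "forced_on")

    @property
    def forced_off(self) -> frozenset[str]:
        return frozenset(g for g, m in self._modes.items() if m.mode == "forced_off")

    @property
    def forced(self) -> frozenset[str]:
        return self.forced_on | self.forced_off

    def phi_vector(self, network: SignedNetwork) -> np.ndarray:
        return np.array([self.mode_of(g).phi for g in network.node_names])

    def validate_for(self, network: SignedNetwork) -> None:
        unknown = [g for g in self._modes if g not in network]
        if unknown:
            raise ValueError(f"ruleset keys not in network: {unknown}")

    def merged_with(self, other: "RuleSet", warn_on_conflict: bool = True) -> "RuleSet":
        """New ruleset with *other*'s modes overriding this one's on conflict."""
        modes = dict(self._modes)
        for g, m in other._modes.items():
            if g in modes and modes[g] != m and warn_on_conflict:
                warnings.warn(
                    f"ruleset merge: {g} {modes[g].mode} overridden by {m.mode}",
                    stacklevel=2,
                )
            modes[g] = m
        label = " + ".join(s for s in (self.label, other.label) if s)
        return RuleSet(modes, label=label)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RuleSet):
            return NotImplemented
        return self._modes == other._modes

    def __repr__(self) -> str:
        on = ",".join(sorted(self.forced_on)) or "-"
        off = ",".join(sorted(self.forced_off)) or "-"
        return f"RuleSet(on=[{on}], off=[{off}], label={self.label!r})"


@dataclass(frozen=True)
class EdgeCutoffs:
    """Screen-to-edge inclusion cutoffs.

    An overexpressed factor gains an activating edge to a promoter when the
    fold-change is >= ``fc_up`` with p < ``p_max``; a repressive edge when the
    fold-change is <= ``fc_down`` with p < ``p_max``.  Defaults reproduce the
    published filter (1.5-fold, p < 0.01); the down cutoff is the reciprocal
    ratio 1/1.5 so a printed FC of 0.63/0.64/0.60 passes.
    """

    fc_up: float = 1.5
    fc_down: float = 1.0 / 1.5
    p_max: float = 0.01

    def __post_init__(self) -> None:
        if not self.fc_up > 1:
            raise ValueError("fc_up must be > 1")
        if not 0 < self.fc_down < 1:
            raise ValueError("fc_down must be in (0, 1)")
        if not 0 < self.p_max < 1:
            raise ValueError("p_max must be in (0, 1)")

    def classify(self, fold_change: float, p_value: float) -> int:
        """+1 (up), -1 (down) or 0 (no edge) for one screen record."""
        if fold_change <= 0:
            raise ValueError(f"fold_change must be positive, got {fold_change}")
        if p_value < self.p_max:
            if fold_change >= self.fc_up:
                return 1
            if fold_change <= self.fc_down:
                return -1
        return 0


# ---------------------------------------------------------------------------
# screen-table operations
# ---------------------------------------------------------------------------

def _as_screen_frame(records) -> pd.DataFrame:
    df = pd.DataFrame(records)
    missing = [c for c in SCREEN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"screen table missing columns: {missing}")
    if (df["fold_change"] <= 0).any():
        bad = df.loc[df["fold_change"] <= 0].iloc[0]
        raise ValueError(
            f"fold_change must be positive "
            f"({bad['perturbation']} on {bad['promoter']}: {bad['fold_change']})"
        )
    return df


def build_network_from_screen(
    records,
    cutoffs: EdgeCutoffs | None = None,
    manual_edges: Iterable[Interaction | tuple] = (),
    target: str = "TERT",
) -> SignedNetwork:
    """Assemble a signed network from overexpression screen records.

    Each record reports the response of ``promoter`` to overexpression of the
    factor in ``perturbation``.  An edge factor -> promoter with sign +1 is
    emitted when ``fold_change >= cutoffs.fc_up`` and ``p < cutoffs.p_max``;
    sign -1 when ``fold_change <= cutoffs.fc_down`` and ``p < cutoffs.p_max``;
    otherwise no edge.  ``manual_edges`` are appended afterwards and override
    any screen-derived edge for the same (source, target) pair -- this is how
    the model's single cutoff relaxation (STAT3 as a TERT activator) enters.

    All genes mentioned anywhere become nodes, ordered by first appearance
    (promoters before perturbation-only genes).
    """
    cutoffs = cutoffs or EdgeCutoffs()
    df = _as_screen_frame(records)

    dup = df.duplicated(subset=["promoter", "perturbation"], keep=False)
    if dup.any():
        pair = df.loc[dup, ["promoter", "perturbation"]].iloc[0]
        raise ValueError(
            f"duplicate screen record for pair "
            f"({pair['perturbation']} -> {pair['promoter']})"
        )

    node_order: list[str] = []
    for g in pd.concat([df["promoter"], df["perturbation"]]):
        if g not in node_order:
            node_order.append(g)

    edges: dict[tuple[str, str], int] = {}
    for row in df.itertuples(index=False):
        sign = cutoffs.classify(row.fold_change, row.p_value)
        if sign:
            edges[(row.perturbation, row.promoter)] = sign

    for it in manual_edges:
        if not isinstance(it, Interaction):
            it = Interaction(*it)
        edges[(it.source, it.target)] = it.sign
        for g in (it.source, it.target):
            if g not in node_order:
                node_order.append(g)

    tgt = target if target in node_order else node_order[0]
    return SignedNetwork(
        node_order, [(s, t, w) for (s, t), w in edges.items()], target=tgt
    )


def derive_overrides_from_treatment(
    records, cutoffs: EdgeCutoffs | None = None, label: str = ""
) -> RuleSet:
    """Turn compound-treatment screen records into a forced-node ruleset.

    Records whose promoter responds significantly up under treatment become
    ``forced_on`` (constitutive activity); significantly down, ``forced_off``.
    Non-significant promoters stay free.  This is the published mapping of
    inhibitor effects (SU6656, FR180204, BIO) onto rule-table modifications.
    """
    cutoffs = cutoffs or EdgeCutoffs()
    df = _as_screen_frame(records)
    if df["promoter"].duplicated().any():
        gene = df.loc[df["promoter"].duplicated(), "promoter"].iloc[0]
        raise ValueError(f"conflicting treatment records for promoter {gene}")

    on, off = [], []
    for row in df.itertuples(index=False):
        sign = cutoffs.classify(row.fold_change, row.p_value)
        if sign == 1:
            on.append(row.promoter)
        elif sign == -1:
            off.append(row.promoter)
    if not label and len(df["perturbation"].unique()) == 1:
        label = str(df["perturbation"].iloc[0])
    return RuleSet.forcing(forced_on=on, forced_off=off, label=label)


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def _load_fixture(name: str) -> SignedNetwork:
    from . import io  # local import to avoid a cycle at package import time

    path = resources.files("tertbn.data") / name
    with resources.as_file(path) as p:
        return io.read_edge_list(p)


def canonical_tert_network() -> SignedNetwork:
    """The canonical 15-node, 92-interaction TERT model.

    50 activating and 42 repressive interactions; TERT has 7 direct
    activators (SP1, MYCN, RELA, MYC, FOS, HIF1A, STAT3) and 7 direct
    repressors (AR, JUN, TP53, E2F1, MXD1, SP3, NR2F2) and out-degree 0.
    """
    return _load_fixture("tert_canonical.tsv")


def ets2_extended_network() -> SignedNetwork:
    """The 16-node ETS2-extended model.

    The canonical model plus ETS2 with its screen-derived neighbourhood:
    repressed by TP53, activated by MYCN, STAT3 and itself; ETS2 activates
    AR and TERT and represses JUN, HIF1A, FOS, SP3, STAT3 and NR2F2.
    Models Ets-factor gain of function at the TERT promoter.
    """
    return _load_fixture("tert_ets2.tsv")


def no_stat3_network() -> SignedNetwork:
    """Canonical model with the STAT3 -> TERT activation dropped.

    The model-selection variant in which the single relaxed-cutoff edge is
    excluded; STAT3 remains a node with its other interactions.
    """
    return _load_fixture("tert_no_stat3.tsv")
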
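"""Synthetic transfection-screen generator.

Produces summary screen tables -- one (factor, promoter) fold-change and
p-value per ordered node pair -- from a planted signed network, so the
screen-to-network construction stage and the downstream pipeline can be
exercised end to end without experimental data.

Fold-changes are log-normal: true activating effects centre on a median
above the inclusion cutoff (default 2.5), true repressive effects below the
reciprocal cutoff (default 0.4), and non-edges fluctuate multiplicatively
around 1.  P-values are drawn directly (uniform, small for true edges and
large for non-edges) rather than derived from simulated replicate assays;
the construction stage consumes only the FC/p summary, and the replicate
count is carried as metadata describing the emulated assay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .netcore import SignedNetwork

__all__ = [
    "SyntheticScreenSpec",
    "RecoveryMetrics",
    "simulate_screen",
    "evaluate_recovery",
]


@dataclass(frozen=True)
class SyntheticScreenSpec:
    """Distributional description of a synthetic reporter screen.

    ``activation_fc`` / ``repression_fc`` are (median, log-scale sd) pairs
    for true effects; ``null_fc_scale`` is the log-scale sd of non-edge
    fold-changes around 1.  Setting a scale to 0 gives the zero-noise
    point-mass limit in which the cutoff filter recovers the planted edges
    exactly.
    """

    planted: SignedNetwork
    activation_fc: tuple[float, float] = (2.5, 0.15)
    repression_fc: tuple[float, float] = (0.4, 0.15)
    null_fc_scale: float = 0.1
    replicates: int = 3
    true_p: tuple[float, float] = (0.0, 0.005)
    null_p: tuple[float, float] = (0.05, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        if not self.activation_fc[0] > 1:
            raise ValueError("activation median must exceed 1")
        if not 0 < self.repression_fc[0] < 1:
            raise ValueError("repression median must lie in (0, 1)")


def simulate_screen(spec: SyntheticScreenSpec) -> pd.DataFrame:
    """One screen record per ordered (factor, promoter) pair.

    Planted edges draw their fold-change from the matching effect
    distribution and their p-value from ``true_p``; non-edges draw a
    fold-change near 1 and a p-value from ``null_p``.  Deterministic under
    ``spec.seed``; exactly ``n_nodes**2`` rows (self-pairs included).
    """
    rng = np.random.default_rng(spec.seed)
    net = spec.planted
    rows = []
    for factor in net.node_names:
        for promoter in net.node_names:
            sign = net.sign(factor, promoter)
            if sign == 1:
                med, sd = spec.activation_fc
                fc = med * np.exp(rng.normal(0.0, sd)) if sd else med
                p = rng.uniform(*spec.true_p)
            elif sign == -1:
                med, sd = spec.repression_fc
                fc = med * np.exp(rng.normal(0.0, sd)) if sd else med
                p = rng.uniform(*spec.true_p)
            else:
                sd = spec.null_fc_scale
                fc = np.exp(rng.normal(0.0, sd)) if sd else 1.0
                p = rng.uniform(*spec.null_p)
            rows.append(
                {
                    "promoter": promoter,
                    "perturbation": factor,
                    "fold_change": float(fc),
                    "p_value": float(max(p, np.nextafter(0, 1))),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RecoveryMetrics:
    """Edge-recovery quality of an inferred network vs the planted truth."""

    precision: float
    recall: float
    sign_accuracy: float
    n_true: int
    n_inferred: int


def evaluate_recovery(planted: SignedNetwork, inferred: SignedNetwork) -> RecoveryMetrics:
    """Unsigned edge precision/recall plus sign accuracy on recovered edges.

    Precision and recall compare (source, target) pairs ignoring signs;
    sign accuracy is the fraction of correctly signed edges among the true
    positives.  Node sets must match.
    """
    if set(planted.node_names) != set(inferred.node_names):
        raise ValueError("planted and inferred networks have different node sets")
    true_edges = {(it.source, it.target): it.sign for it in planted.interactions}
    inf_edges = {(it.source, it.target): it.sign for it in inferred.interactions}
    tp = set(true_edges) & set(inf_edges)
    precision = len(tp) / len(inf_edges) if inf_edges else 0.0
    recall = len(tp) / len(true_edges) if true_edges else 0.0
    sign_acc = (
        sum(1 for e in tp if true_edges[e] == inf_edges[e]) / len(tp) if tp else 0.0
    )
    return RecoveryMetrics(
        precision=precision,
        recall=recall,
        sign_accuracy=sign_acc,
        n_true=len(true_edges),
        n_inferred=len(inf_edges),
    )
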
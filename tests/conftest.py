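import numpy as np
import pytest

import tertbn as tb

GENES_15 = (
    "AR", "JUN", "TP53", "SP1", "E2F1", "MYCN", "MXD1", "RELA",
    "MYC", "FOS", "HIF1A", "SP3", "STAT3", "NR2F2", "TERT",
)


@pytest.fixture(scope="session")
def canonical():
    return tb.canonical_tert_network()


@pytest.fixture(scope="session")
def ets2():
    return tb.ets2_extended_network()


@pytest.fixture(scope="session")
def basal_space(canonical):
    return tb.enumerate_statespace(canonical, tb.RuleSet.basal())


@pytest.fixture(scope="session")
def bio_rules():
    return tb.RuleSet.forcing(forced_on=["STAT3"], forced_off=["FOS"], label="BIO")


@pytest.fixture(scope="session")
def bio_space(canonical, bio_rules):
    return tb.enumerate_statespace(canonical, bio_rules)


@pytest.fixture
def toy3():
    """A -| B, B -> C, C -| A."""
    return tb.SignedNetwork(
        ["A", "B", "C"], [("A", "B", -1), ("B", "C", 1), ("C", "A", -1)], target="C"
    )


def random_signed_network(rng: np.random.Generator, n: int = 4) -> tb.SignedNetwork:
    """Small random network for oracle cross-checks (target = last node)."""
    names = [f"G{i}" for i in range(n)]
    edges = []
    for s in names:
        for t in names:
            if rng.random() < 0.4:
                edges.append((s, t, 1 if rng.random() < 0.5 else -1))
    return tb.SignedNetwork(names, edges, target=names[-1])
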
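"""Network types, screen-based construction and packaged fixtures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tertbn as tb
from tertbn.netcore import SCREEN_COLUMNS

from conftest import GENES_15


def make_records(rows):
    return pd.DataFrame(rows, columns=list(SCREEN_COLUMNS))


class TestEdgeCutoffs:
    @pytest.mark.parametrize(
        "fc,p,expected",
        [
            (2.59, 0.0048, 1),   # SU6656 JUN: clear up-regulation
            (1.99, 0.0092, 1),   # p just under 0.01 passes (strict <)
            (1.5, 0.005, 1),     # FC cutoff is inclusive
            (0.63, 0.0083, -1),  # FR180204 TP53: 0.63 <= 1/1.5
            (0.64, 0.0088, -1),  # BIO FOS
            (0.60, 0.0037, -1),
            (1.0, 0.5, 0),       # below both cutoffs
            (2.0, 0.01, 0),      # p == p_max fails (strict <)
            (1.49, 0.001, 0),
            (0.67, 0.001, 0),    # above the 1/1.5 down cutoff
        ],
    )
    def test_classify(self, fc, p, expected):
        assert tb.EdgeCutoffs().classify(fc, p) == expected

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            tb.EdgeCutoffs(fc_up=0.9)
        with pytest.raises(ValueError):
            tb.EdgeCutoffs(fc_down=1.2)
        with pytest.raises(ValueError):
            tb.EdgeCutoffs().classify(-1.0, 0.001)


class TestBuildFromScreen:
    def test_edges_follow_cutoffs_and_manual_override(self):
        records = make_records(
            [
                ("TERT", "STAT3", 1.3, 0.2),   # not significant in the screen
                ("TERT", "MYC", 2.0, 0.001),   # activator
                ("TERT", "TP53", 0.5, 0.001),  # repressor
                ("MYC", "TP53", 1.0, 0.5),     # no edge
            ]
        )
        net = tb.build_network_from_screen(
            records, manual_edges=[("STAT3", "TERT", 1)]
        )
        assert net.sign("STAT3", "TERT") == 1  # retained by the manual decision
        assert net.sign("MYC", "TERT") == 1
        assert net.sign("TP53", "TERT") == -1
        assert net.sign("TP53", "MYC") is None
        assert set(net.node_names) == {"TERT", "MYC", "TP53", "STAT3"}

    def test_each_record_yields_at_most_one_edge(self):
        records = make_records(
            [("P", "F", fc, 0.001) for fc in (0.1, 0.5, 1.0, 1.5, 3.0)]
        )
        with pytest.raises(ValueError, match="duplicate"):
            tb.build_network_from_screen(records)
        for fc in (0.1, 1.0, 3.0):
            net = tb.build_network_from_screen(make_records([("P", "F", fc, 0.001)]))
            assert net.n_interactions <= 1

    def test_duplicate_pair_names_the_pair(self):
        records = make_records([("P", "F", 2.0, 0.001), ("P", "F", 2.1, 0.001)])
        with pytest.raises(ValueError, match=r"F -> P"):
            tb.build_network_from_screen(records)

    def test_nonpositive_fold_change_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            tb.build_network_from_screen(make_records([("P", "F", 0.0, 0.001)]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.randoms(use_true_random=False))
    def test_record_order_irrelevant(self, rnd):
        rows = [
            ("TERT", "MYC", 2.0, 0.001),
            ("TERT", "TP53", 0.5, 0.002),
            ("MYC", "E2F1", 1.8, 0.003),
            ("TP53", "MYC", 0.4, 0.004),
            ("E2F1", "E2F1", 73.5, 0.001),
        ]
        base = tb.build_network_from_screen(make_records(rows), target="TERT")
        shuffled = list(rows)
        rnd.shuffle(shuffled)
        permuted = tb.build_network_from_screen(make_records(shuffled), target="TERT")
        assert {(i.source, i.target, i.sign) for i in base.interactions} == {
            (i.source, i.target, i.sign) for i in permuted.interactions
        }

    def test_zero_noise_synthetic_table_recovers_planted(self):
        planted = tb.SignedNetwork(
            ["A", "B", "C", "D", "T"],
            [("A", "T", 1), ("B", "T", -1), ("C", "T", 1), ("D", "T", -1),
             ("A", "B", 1), ("B", "C", -1), ("C", "D", 1), ("D", "A", -1),
             ("A", "C", 1), ("B", "D", -1)],
            target="T",
        )
        spec = tb.SyntheticScreenSpec(
            planted=planted, activation_fc=(2.5, 0.0), repression_fc=(0.4, 0.0),
            null_fc_scale=0.0, true_p=(0.001, 0.0011), null_p=(0.5, 0.51), seed=0,
        )
        inferred = tb.build_network_from_screen(tb.simulate_screen(spec), target="T")
        assert {(i.source, i.target, i.sign) for i in inferred.interactions} == {
            (i.source, i.target, i.sign) for i in planted.interactions
        }


class TestTreatmentOverrides:
    @pytest.mark.parametrize(
        "rows,on,off",
        [
            (  # SU6656: five repressor promoters up
                [("JUN", "SU6656", 2.59, 0.0048), ("TP53", "SU6656", 1.99, 0.0092),
                 ("MYCN", "SU6656", 3.19, 0.0089), ("MXD1", "SU6656", 1.84, 0.0081),
                 ("SP3", "SU6656", 2.5, 0.005)],
                {"JUN", "TP53", "MYCN", "MXD1", "SP3"}, set(),
            ),
            (  # FR180204: TP53 and FOS down
                [("TP53", "FR180204", 0.63, 0.0083), ("FOS", "FR180204", 0.6, 0.0037)],
                set(), {"TP53", "FOS"},
            ),
            (  # BIO: FOS down, STAT3 up
                [("FOS", "BIO", 0.64, 0.0088), ("STAT3", "BIO", 2.77, 0.0017)],
                {"STAT3"}, {"FOS"},
            ),
        ],
    )
    def test_inhibitor_rulesets(self, rows, on, off):
        rules = tb.derive_overrides_from_treatment(make_records(rows))
        assert rules.forced_on == frozenset(on)
        assert rules.forced_off == frozenset(off)

    def test_conflicting_promoter_records_rejected(self):
        rows = [("FOS", "BIO", 0.64, 0.001), ("FOS", "BIO2", 2.0, 0.001)]
        with pytest.raises(ValueError, match="conflicting"):
            tb.derive_overrides_from_treatment(make_records(rows))


class TestCanonicalNetwork:
    def test_node_panel_and_order(self, canonical):
        assert canonical.node_names == GENES_15
        assert canonical.target == "TERT"

    def test_interaction_census(self, canonical):
        signs = [i.sign for i in canonical.interactions]
        assert len(signs) == 92
        assert signs.count(1) == 50
        assert signs.count(-1) == 42

    def test_tert_neighbourhood(self, canonical):
        assert canonical.in_degree("TERT") == 14
        assert canonical.out_degree("TERT") == 0
        assert set(canonical.activators_of("TERT")) == {
            "SP1", "MYCN", "RELA", "MYC", "FOS", "HIF1A", "STAT3"
        }
        assert set(canonical.repressors_of("TERT")) == {
            "AR", "JUN", "TP53", "E2F1", "MXD1", "SP3", "NR2F2"
        }

    def test_fos_edge_carries_screen_direction(self, canonical):
        # literature reports FOS as a TERT inhibitor; the screen direction wins
        assert canonical.sign("FOS", "TERT") == 1

    def test_every_regulator_touches_tert_directly(self, canonical):
        for node in canonical.node_names:
            if node != "TERT":
                assert canonical.sign(node, "TERT") in (1, -1)

    def test_tert_roles(self, canonical):
        roles = {n.name: n.tert_role for n in canonical.nodes}
        assert roles["TERT"] == "target"
        assert roles["MYC"] == "activator"
        assert roles["TP53"] == "repressor"


class TestVariantNetworks:
    def test_ets2_extension(self, ets2):
        assert ets2.n_nodes == 16
        assert ets2.node_names[:15] == GENES_15
        assert ets2.node_names[15] == "ETS2"
        assert ets2.sign("ETS2", "TERT") == 1
        assert ets2.sign("TP53", "ETS2") == -1
        assert ets2.sign("MYCN", "ETS2") == 1
        assert ets2.sign("ETS2", "ETS2") == 1
        assert ets2.n_interactions == 92 + 12

    def test_no_stat3_drops_single_edge(self, canonical):
        variant = tb.no_stat3_network()
        assert variant.n_nodes == 15
        assert variant.sign("STAT3", "TERT") is None
        assert variant.n_interactions == 91
        assert variant.sign("STAT3", "JUN") == 1  # other STAT3 edges remain


class TestRuleSet:
    def test_conflicting_forcing_rejected(self):
        with pytest.raises(ValueError, match="both"):
            tb.RuleSet.forcing(forced_on=["A"], forced_off=["A"])

    def test_merge_overrides_with_warning(self):
        base = tb.RuleSet.forcing(forced_off=["MYC"], label="MYC-off")
        extra = tb.RuleSet.forcing(forced_on=["MYC"], label="MYC-on")
        with pytest.warns(UserWarning, match="overridden"):
            merged = base.merged_with(extra)
        assert merged.forced_on == frozenset({"MYC"})

    def test_unknown_gene_rejected_against_network(self, canonical):
        rules = tb.RuleSet.forcing(forced_on=["NOTAGENE"])
        with pytest.raises(ValueError, match="NOTAGENE"):
            rules.validate_for(canonical)
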
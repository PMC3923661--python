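"""Constitutive perturbation scans, bit-flip noise and rule-set shifts."""

import pytest

import tertbn as tb


def stable_on(frame, label):
    return float(frame.loc[frame["spec_label"] == label, "stable_on_fraction"].iloc[0])


class TestPerturbationScan:
    def test_myc_and_fos_suppression_ablate_on_states(self, canonical):
        specs = [
            tb.PerturbationSpec({"MYC": "forced_off"}, label="MYC-off"),
            tb.PerturbationSpec({"FOS": "forced_off"}, label="FOS-off"),
        ]
        out = tb.perturbation_scan(canonical, tb.RuleSet.basal(), specs)
        assert stable_on(out, "MYC-off") == 0.0
        assert stable_on(out, "FOS-off") == 0.0

    def test_mycn_suppression_fractionates_statespace(self, canonical):
        out = tb.perturbation_scan(
            canonical,
            tb.RuleSet.basal(),
            [tb.PerturbationSpec({"MYCN": "forced_off"}, label="MYCN-off")],
        )
        detail = out["attractor_detail"].iloc[0]
        fracs = {
            cls: sorted(round(100 * f, 1) for c, f in detail if c == cls)
            for cls in ("stable_off", "stable_on", "oscillating")
        }
        assert fracs["stable_off"] == [5.7, 63.5]
        assert fracs["stable_on"] == [25.7]
        assert fracs["oscillating"] == [5.0]

    def test_double_scan_on_myc_suppressed_background(self, canonical):
        base = tb.RuleSet.forcing(forced_off=["MYC"], label="MYC-off")
        out = tb.perturbation_scan(
            canonical,
            base,
            [
                tb.PerturbationSpec({"AR": "forced_off"}, label="AR-off"),
                tb.PerturbationSpec({"SP3": "forced_off"}, label="SP3-off"),
                tb.PerturbationSpec({"MXD1": "forced_off"}, label="MXD1-off"),
            ],
        )
        assert stable_on(out, "AR-off") > 0.99  # near-complete recovery
        assert round(100 * stable_on(out, "SP3-off"), 1) == 8.9
        assert stable_on(out, "MXD1-off") < 0.05

    def test_empty_spec_list_returns_base_summary(self, canonical):
        out = tb.perturbation_scan(canonical, tb.RuleSet.basal(), [])
        assert len(out) == 1
        assert out["stable_on_fraction"].iloc[0] == 1.0
        assert out["n_attractors"].iloc[0] == 2

    def test_fractions_sum_to_one(self, canonical):
        out = tb.perturbation_scan(
            canonical,
            tb.RuleSet.basal(),
            [tb.PerturbationSpec({"MYCN": "forced_off"}, label="s")],
        )
        detail = out["attractor_detail"].iloc[0]
        assert sum(f for _, f in detail) == pytest.approx(1.0)
        on = sum(f for c, f in detail if c == "stable_on")
        assert on == pytest.approx(out["stable_on_fraction"].iloc[0])

    def test_forcing_target_rejected(self, canonical):
        spec = tb.PerturbationSpec({"TERT": "forced_on"}, label="bad")
        with pytest.raises(ValueError, match="target"):
            tb.perturbation_scan(canonical, tb.RuleSet.basal(), [spec])

    def test_empty_forced_map_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            tb.PerturbationSpec({}, label="empty")


class TestDirectionSpecs:
    def test_canonical_direction_map(self, canonical):
        specs = tb.default_direction_specs(canonical)
        assert len(specs) == 14
        directions = {
            list(s.forced)[0]: list(s.forced.values())[0] for s in specs
        }
        off = {g for g, m in directions.items() if m == "forced_off"}
        on = {g for g, m in directions.items() if m == "forced_on"}
        assert off == {"SP1", "MYCN", "RELA", "MYC", "FOS", "HIF1A", "STAT3"}
        assert on == {"AR", "JUN", "TP53", "E2F1", "MXD1", "SP3", "NR2F2"}

    def test_ets2_adds_forced_off_spec(self, ets2):
        specs = tb.default_direction_specs(ets2)
        assert len(specs) == 15
        ets2_spec = [s for s in specs if "ETS2" in s.forced][0]
        assert ets2_spec.forced["ETS2"] == "forced_off"

    def test_co_suppression_specs_all_off(self, canonical):
        specs = tb.co_suppression_specs(canonical)
        assert len(specs) == 14
        assert all(set(s.forced.values()) == {"forced_off"} for s in specs)

    def test_node_without_target_edge_reported(self):
        net = tb.SignedNetwork(
            ["A", "B", "T"], [("A", "T", 1), ("A", "B", 1)], target="T"
        )
        with pytest.raises(ValueError, match="B"):
            tb.default_direction_specs(net)


class TestBitflip:
    def test_basal_flip_counts(self, canonical, basal_space):
        rules = tb.RuleSet.basal()
        s1 = basal_space.basins[0].attractor.cycle[0]
        s2 = basal_space.basins[1].attractor.cycle[0]
        f1 = tb.bitflip_map(canonical, rules, s1)
        f2 = tb.bitflip_map(canonical, rules, s2)
        assert len(f1) == len(f2) == 14  # TERT itself is never flipped
        assert sum(r.switched for r in f1) == 8
        assert sum(r.switched for r in f2) == 5

    def test_bio_flip_counts(self, canonical, bio_rules, bio_space):
        b1 = bio_space.basins[0].attractor.cycle[0]  # dominant, TERT off
        b2 = bio_space.basins[1].attractor.cycle[0]
        f1 = tb.bitflip_map(canonical, bio_rules, b1)
        f2 = tb.bitflip_map(canonical, bio_rules, b2)
        assert sum(r.switched for r in f1) == 2
        assert sum(r.switched for r in f2) == 7

    def test_jun_noise_switches_every_steady_state(
        self, canonical, basal_space, bio_rules, bio_space
    ):
        for rules, space in ((tb.RuleSet.basal(), basal_space), (bio_rules, bio_space)):
            for basin in space.basins:
                flips = tb.bitflip_map(canonical, rules, basin.attractor.cycle[0])
                jun = [r for r in flips if r.flipped_node == "JUN"][0]
                assert jun.switched

    def test_flip_at_forced_node_never_switches(self, canonical, bio_rules, bio_space):
        for basin in bio_space.basins:
            flips = tb.bitflip_map(canonical, bio_rules, basin.attractor.cycle[0])
            for r in flips:
                if r.flipped_node in ("FOS", "STAT3"):
                    assert not r.switched

    def test_destinations_are_attractors_of_same_ruleset(
        self, canonical, bio_rules, bio_space
    ):
        cycles = {b.attractor.cycle for b in bio_space.basins}
        flips = tb.bitflip_map(
            canonical, bio_rules, bio_space.basins[0].attractor.cycle[0]
        )
        assert all(r.destination.cycle in cycles for r in flips)

    def test_non_fixed_point_rejected(self, canonical):
        with pytest.raises(ValueError, match="not a fixed point"):
            tb.bitflip_map(canonical, tb.RuleSet.basal(), 0)


class TestRulesetShift:
    def test_basal_to_bio_and_back(self, canonical, basal_space, bio_rules, bio_space):
        s1 = basal_space.basins[0].attractor.cycle[0]
        s2 = basal_space.basins[1].attractor.cycle[0]
        b1 = bio_space.basins[0].attractor.cycle[0]
        b2 = bio_space.basins[1].attractor.cycle[0]
        basal = tb.RuleSet.basal()
        assert tb.ruleset_shift(canonical, s1, bio_rules).cycle == (b1,)
        assert tb.ruleset_shift(canonical, s2, bio_rules).cycle == (b2,)
        # wear-off: both inhibitor states collapse to basal state 1
        assert tb.ruleset_shift(canonical, b1, basal).cycle == (s1,)
        assert tb.ruleset_shift(canonical, b2, basal).cycle == (s1,)

    def test_shift_classifies_target(self, canonical, basal_space, bio_rules):
        s1 = basal_space.basins[0].attractor.cycle[0]
        attr = tb.ruleset_shift(canonical, s1, bio_rules)
        assert attr.target_class == "stable_off"

    def test_identity_shift_is_fixed(self, canonical, basal_space):
        s1 = basal_space.basins[0].attractor.cycle[0]
        attr = tb.ruleset_shift(canonical, s1, tb.RuleSet.basal())
        assert attr.cycle == (s1,)
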
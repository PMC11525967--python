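"""Lineage records, fate rules, sister analysis and cycle series."""

from __future__ import annotations

import math

import numpy as np
import pytest

import lineagefish as lf
from lineagefish.lineage import (
    CELL_DEATH,
    CELL_DEATH_BLOCKED,
    LOST,
    MOTHER_DIES,
    MOTHER_DIVISION_BLOCKED,
    CellNeverDividedError,
    LineageNode,
    LineageRecord,
    generation,
    mother_name,
    sister_name,
)


def two_daughter_record(
    mother="ABalaapap",
    birth=0.0,
    division=42.0,
    cand_corpse=None,
    cand_observed=None,
    sister_division=None,
    sister_observed=None,
    mother_corpse=None,
):
    """A minimal mother + two daughters record for rule tests."""
    nodes = []
    if mother_corpse is not None:
        nodes.append(LineageNode(mother, birth, corpse_min=mother_corpse))
        return LineageRecord("e1", nodes)
    nodes.append(LineageNode(mother, birth, division_min=division))
    if division is not None:
        nodes.append(LineageNode(
            mother + "a", division, corpse_min=cand_corpse,
            last_observed_min=cand_observed, parent=mother))
        nodes.append(LineageNode(
            mother + "p", division, division_min=sister_division,
            last_observed_min=sister_observed, parent=mother))
    return LineageRecord("e1", nodes)


class TestRecordValidation:
    def test_three_node_tree(self):
        rec = two_daughter_record(cand_observed=50.0, sister_observed=50.0)
        assert len(rec) == 3
        assert rec["ABalaapap"].children == ["ABalaapapa", "ABalaapapp"]

    def test_daughter_before_mother_rejected(self):
        with pytest.raises(ValueError, match="before its mother"):
            LineageRecord("e1", [
                LineageNode("ABa", 10.0, division_min=20.0),
                LineageNode("ABaa", 5.0, parent="ABa"),
            ])

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            LineageRecord("e1", [
                LineageNode("ABa", 0.0), LineageNode("ABa", 1.0)])

    def test_orphan_parent_rejected(self):
        with pytest.raises(ValueError, match="orphan"):
            LineageRecord("e1", [LineageNode("ABaa", 0.0, parent="ABa")])

    def test_division_and_corpse_mutually_exclusive(self):
        with pytest.raises(ValueError, match="both divide"):
            LineageNode("ABa", 0.0, division_min=5.0, corpse_min=6.0)

    def test_event_before_birth_rejected(self):
        with pytest.raises(ValueError, match="precedes birth"):
            LineageNode("ABa", 10.0, division_min=5.0)


class TestNames:
    @pytest.mark.parametrize("name,mother,sister", [
        ("ABalaapapa", "ABalaapap", "ABalaapapp"),
        ("MSpaapp", "MSpaap", "MSpaapa"),
        ("QL.pp", "QL.p", "QL.pa"),
    ])
    def test_mother_and_sister(self, name, mother, sister):
        assert mother_name(name) == mother
        assert sister_name(name) == sister

    def test_first_wave_generations(self):
        # the 13 AB-derived deaths occur after the 9th division round,
        # the MS-derived death (MSpaapp) after the 8th
        assert generation("ABalaapapa") == 9
        assert generation("ABarpppppp") == 9
        assert generation("MSpaapp") == 8
        assert generation(mother_name("ABalaapapa")) == 8


class TestElementaryMeasures:
    def test_cycle_length_is_division_minus_birth(self):
        node = LineageNode("ABa", 0.0, division_min=42.0)
        assert lf.cell_cycle_length(node) == 42.0

    def test_degenerate_division_warns(self):
        node = LineageNode("ABa", 10.0, division_min=10.0)
        with pytest.warns(UserWarning, match="degenerate"):
            assert lf.cell_cycle_length(node) == 0.0

    def test_never_divided_is_distinct_error(self):
        node = LineageNode("ABa", 0.0, last_observed_min=100.0)
        with pytest.raises(CellNeverDividedError):
            lf.cell_cycle_length(node)

    def test_time_to_corpse(self):
        node = LineageNode("ABaa", 100.0, corpse_min=123.6)
        assert lf.time_to_corpse(node) == pytest.approx(23.6)

    def test_time_to_corpse_requires_corpse(self):
        with pytest.raises(ValueError, match="no corpse"):
            lf.time_to_corpse(LineageNode("ABaa", 0.0))


class TestDeathFateClassifier:
    def test_corpse_within_threshold_is_death(self):
        rec = two_daughter_record(cand_corpse=72.0, sister_observed=130.0)
        call = lf.classify_death_fate(rec, "ABalaapapa")
        assert call.category == CELL_DEATH
        assert call.time_to_corpse_min == pytest.approx(30.0)

    def test_no_corpse_observed_past_twice_mother_cycle_is_blocked(self):
        rec = two_daughter_record(cand_observed=132.0, sister_observed=132.0)
        call = lf.classify_death_fate(rec, "ABalaapapa")
        assert call.category == CELL_DEATH_BLOCKED

    def test_short_observation_is_lost(self):
        rec = two_daughter_record(cand_observed=92.0, sister_observed=92.0)
        # threshold: 42 + 2*42 = 126 min; observed only to 92
        call = lf.classify_death_fate(rec, "ABalaapapa")
        assert call.category == LOST

    def test_mother_without_division_is_mother_blocked(self):
        rec = LineageRecord("e1", [
            LineageNode("ABalaapap", 0.0, last_observed_min=200.0)])
        call = lf.classify_death_fate(rec, "ABalaapapa")
        assert call.category == MOTHER_DIVISION_BLOCKED

    def test_mother_corpse_is_mother_dies(self):
        rec = two_daughter_record(mother_corpse=30.0)
        call = lf.classify_death_fate(rec, "ABalaapapa")
        assert call.category == MOTHER_DIES

    def test_missing_mother_raises(self):
        rec = LineageRecord("e1", [LineageNode("MSpaap", 0.0)])
        with pytest.raises(ValueError, match="mother"):
            lf.classify_death_fate(rec, "ABalaapapa")

    def test_next_round_start_shortens_deadline(self):
        # sister divides at 100; candidate without corpse observed to 110:
        # blocked via the next-round criterion even though 2x cycle = 126
        rec = two_daughter_record(
            cand_observed=110.0, sister_division=100.0)
        call = lf.classify_death_fate(rec, "ABalaapapa")
        assert call.category == CELL_DEATH_BLOCKED
        assert call.deadline_min == pytest.approx(100.0)

    def test_next_round_criterion_can_be_disabled(self):
        rec = two_daughter_record(
            cand_observed=110.0, sister_division=100.0)
        rules = lf.FateRuleConfig(also_blocked_if_next_round_started=False)
        call = lf.classify_death_fate(rec, "ABalaapapa", rules)
        assert call.category == LOST  # observed only to 110 < 126

    def test_partition_exactly_one_category(self, psf2_records_large):
        records, _ = psf2_records_large
        cats = set()
        for rec in records[:50]:
            for cand in lf.DEFAULT_AB_CANDIDATES:
                a = lf.classify_death_fate(rec, cand)
                b = lf.classify_death_fate(rec, cand)
                assert a.category == b.category  # idempotent
                cats.add(a.category)
        assert cats <= {CELL_DEATH, CELL_DEATH_BLOCKED, LOST,
                        MOTHER_DIVISION_BLOCKED, MOTHER_DIES}

    def test_ground_truth_agreement_on_simulated_records(self):
        """Classifier reproduces generator labels exactly (≥200 candidates)."""
        records, truth = lf.simulate_lineage("psf2_like", n_embryos=20, seed=7)
        n = 0
        for rec in records:
            for cand in lf.DEFAULT_AB_CANDIDATES:
                call = lf.classify_death_fate(rec, cand)
                assert call.category == truth.fate_labels[(rec.embryo_id, cand)]
                n += 1
        assert n >= 200

    def test_raising_threshold_never_unblocks_a_death(self):
        """Monotonicity: cell_death never becomes cell_death_blocked."""
        records, _ = lf.simulate_lineage("psf2_like", n_embryos=10, seed=17)
        for factor in (2.5, 4.0, 8.0):
            rules = lf.FateRuleConfig(block_threshold_factor=factor)
            for rec in records:
                for cand in lf.DEFAULT_AB_CANDIDATES:
                    base = lf.classify_death_fate(rec, cand)
                    alt = lf.classify_death_fate(rec, cand, rules)
                    if base.category == CELL_DEATH:
                        assert alt.category != CELL_DEATH_BLOCKED


class TestPercentBlocked:
    def test_all_death_zero_percent(self):
        calls = [lf.FateCall(f"c{i}", CELL_DEATH) for i in range(13)]
        assert lf.percent_blocked(calls) == 0.0

    def test_all_blocked_hundred_percent(self):
        calls = [lf.FateCall(f"c{i}", CELL_DEATH_BLOCKED) for i in range(13)]
        assert lf.percent_blocked(calls) == 100.0

    def test_lost_excluded_from_denominator(self):
        calls = (
            [lf.FateCall("a", CELL_DEATH_BLOCKED)] * 2
            + [lf.FateCall("b", CELL_DEATH)] * 2
            + [lf.FateCall("c", LOST)]
        )
        assert lf.percent_blocked(calls) == 50.0

    def test_no_scoreable_candidates_is_nan(self):
        calls = [lf.FateCall("a", LOST), lf.FateCall("b", MOTHER_DIES)]
        assert math.isnan(lf.percent_blocked(calls))

    def test_simulated_extremes_are_exact(self):
        for regime, expected in (("wild_type", 0.0), ("ced3_like", 100.0)):
            records, _ = lf.simulate_lineage(regime, n_embryos=4, seed=1)
            calls = [
                lf.classify_death_fate(rec, cand)
                for rec in records for cand in lf.DEFAULT_AB_CANDIDATES
            ]
            assert lf.percent_blocked(calls) == expected


class TestSisterFates:
    def test_divided_and_dead_sisters(self):
        rec = two_daughter_record(cand_corpse=72.0, sister_division=130.0)
        assert lf.classify_sister_fate(rec, "ABalaapapa") == "divided"
        rec2 = LineageRecord("e1", [
            LineageNode("ABalaapap", 0.0, division_min=42.0),
            LineageNode("ABalaapapa", 42.0, corpse_min=70.0,
                        parent="ABalaapap"),
            LineageNode("ABalaapapp", 42.0, corpse_min=75.0,
                        parent="ABalaapap"),
        ])
        assert lf.classify_sister_fate(rec2, "ABalaapapa") == "inappropriate_death"

    def test_mother_phenotype_is_not_applicable(self):
        rec = LineageRecord("e1", [
            LineageNode("ABalaapap", 0.0, last_observed_min=300.0)])
        assert lf.classify_sister_fate(rec, "ABalaapapa") == "not_applicable"

    def test_missing_sister_counts_as_lost_with_warning(self):
        rec = LineageRecord("e1", [
            LineageNode("ABalaapap", 0.0, division_min=42.0),
            LineageNode("ABalaapapa", 42.0, corpse_min=70.0,
                        parent="ABalaapap"),
        ])
        with pytest.warns(UserWarning, match="missing"):
            assert lf.classify_sister_fate(rec, "ABalaapapa") == "lost"

    def test_block_fraction_recovered_binomially(self):
        """Sister division-block fraction ≈ 0.342 over ≥500 applicable draws."""
        records, _ = lf.simulate_lineage("psf2_like", n_embryos=90, seed=31)
        tab = lf.sister_fate_analysis(records, lf.DEFAULT_AB_CANDIDATES)
        n_app = int(tab.loc[["divided", "division_blocked",
                             "inappropriate_death"], "count"].sum())
        assert n_app >= 500
        frac = tab.loc["division_blocked", "fraction_applicable"]
        se = np.sqrt(0.342 * 0.658 / n_app)
        assert abs(frac - 0.342) < 3 * se


class TestCycleSeries:
    def make_chain(self):
        return LineageRecord("e1", [
            LineageNode("ABarp", 0.0, division_min=10.0),
            LineageNode("ABarpp", 10.0, division_min=30.0, parent="ABarp"),
            LineageNode("ABarppp", 30.0, last_observed_min=40.0,
                        parent="ABarpp"),
        ])

    def test_hand_built_chain(self):
        assert lf.lineage_cycle_series(
            self.make_chain(), "ABarppp", "ABarp") == [10.0, 20.0]

    def test_terminal_equals_start_is_empty(self):
        assert lf.lineage_cycle_series(self.make_chain(), "ABarp", "ABarp") == []

    def test_broken_path_names_the_gap(self):
        with pytest.raises(ValueError, match="breaks at"):
            lf.lineage_cycle_series(self.make_chain(), "ABarppp", "MSp")
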
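"""Sibling identification, SLC labelling rules and cohort windows."""

import numpy as np
import pandas as pd
import pytest

from scdmort.sibling_linkage import (
    add_under5_death,
    assign_slc,
    cohort_filter,
    link_siblings,
)

from conftest import make_birth_history, make_roster


def _link(roster_rows, bh_rows):
    return link_siblings(make_roster(roster_rows), make_birth_history(bh_rows))


class TestLinkSiblings:
    def test_full_siblings_share_household_and_mother(self):
        ch = _link(
            [{"child_id": "t1", "household_id": 1}],
            [
                {"child_id": "t1", "household_id": 1, "mother_id": "m1"},
                {"child_id": "u1", "household_id": 1, "mother_id": "m1",
                 "birth_offset_months": 80},
            ],
        )
        groups = ch.set_index("child_id")["sibling_group_id"]
        assert groups["t1"] == groups["u1"]

    def test_half_siblings_not_grouped(self):
        # same mother, different household -> different full-sibling groups
        ch = _link(
            [{"child_id": "t1", "household_id": 1}],
            [
                {"child_id": "t1", "household_id": 1, "mother_id": "m1"},
                {"child_id": "u1", "household_id": 2, "mother_id": "m1"},
            ],
        )
        groups = ch.set_index("child_id")["sibling_group_id"]
        assert groups["t1"] != groups["u1"]

    def test_unlinked_tested_child_retained_and_flagged(self):
        ch = _link(
            [{"child_id": "t1", "household_id": 1},
             {"child_id": "t2", "household_id": 1}],
            [{"child_id": "t2", "household_id": 1, "mother_id": "m1"}],
        )
        row = ch.set_index("child_id").loc["t1"]
        assert bool(row["tested"]) and not bool(row["linked"])

    def test_duplicate_child_ids_error(self):
        with pytest.raises(ValueError, match="duplicate"):
            _link(
                [{"child_id": "t1"}, {"child_id": "t1"}],
                [{"child_id": "t1", "mother_id": "m1"}],
            )

    def test_untested_child_inherits_design_from_household(self):
        ch = _link(
            [{"child_id": "t1", "household_id": 1, "cluster_id": 42,
              "stratum_id": 7, "weight": 1.7}],
            [
                {"child_id": "t1", "household_id": 1, "mother_id": "m1"},
                {"child_id": "u1", "household_id": 1, "mother_id": "m1"},
            ],
        )
        row = ch.set_index("child_id").loc["u1"]
        assert row["cluster_id"] == 42 and row["weight"] == pytest.approx(1.7)


class TestAssignSlc:
    def _label(self, roster_rows, bh_rows):
        return assign_slc(_link(roster_rows, bh_rows)).set_index("child_id")[
            "slc_label"
        ]

    def test_most_severe_genotype_wins(self):
        lab = self._label(
            [
                {"child_id": "a", "household_id": 1, "genotype": "AA"},
                {"child_id": "b", "household_id": 1, "genotype": "AS"},
            ],
            [
                {"child_id": "a", "household_id": 1, "mother_id": "m1"},
                {"child_id": "b", "household_id": 1, "mother_id": "m1"},
            ],
        )
        assert lab["a"] == "Trait" and lab["b"] == "Trait"

    def test_scd_dominates(self):
        lab = self._label(
            [
                {"child_id": "a", "household_id": 1, "genotype": "AA"},
                {"child_id": "b", "household_id": 1, "genotype": "SS"},
            ],
            [
                {"child_id": "a", "household_id": 1, "mother_id": "m1"},
                {"child_id": "b", "household_id": 1, "mother_id": "m1"},
            ],
        )
        assert (lab[["a", "b"]] == "SCD").all()

    def test_half_sibling_scd_label_capped_at_trait(self):
        # u1 shares only the mother with tested SS child t1
        lab = self._label(
            [{"child_id": "t1", "household_id": 1, "genotype": "SS"}],
            [
                {"child_id": "t1", "household_id": 1, "mother_id": "m1"},
                {"child_id": "u1", "household_id": 2, "mother_id": "m1",
                 "birth_offset_months": 90},
            ],
        )
        assert lab["t1"] == "SCD" and lab["u1"] == "Trait"

    def test_aa_group_promoted_by_scd_half_siblings(self):
        # two mothers in one household: m1's group tests AA, m2's tests SC
        lab = self._label(
            [
                {"child_id": "a", "household_id": 1, "genotype": "AA"},
                {"child_id": "b", "household_id": 1, "genotype": "SC"},
            ],
            [
                {"child_id": "a", "household_id": 1, "mother_id": "m1"},
                {"child_id": "b", "household_id": 1, "mother_id": "m2"},
            ],
        )
        assert lab["a"] == "Trait" and lab["b"] == "SCD"

    def test_trait_half_sibling_label_not_capped(self):
        lab = self._label(
            [{"child_id": "t1", "household_id": 1, "genotype": "AC"}],
            [
                {"child_id": "t1", "household_id": 1, "mother_id": "m1"},
                {"child_id": "u1", "household_id": 2, "mother_id": "m1"},
            ],
        )
        assert lab["u1"] == "Trait"

    def test_no_tested_relative_unlabelled(self):
        lab = self._label(
            [{"child_id": "t1", "household_id": 1, "genotype": "AA"}],
            [
                {"child_id": "t1", "household_id": 1, "mother_id": "m1"},
                {"child_id": "u1", "household_id": 9, "mother_id": "m9"},
            ],
        )
        assert pd.isna(lab["u1"])

    def test_other_genotype_excluded_from_evidence(self):
        lab = self._label(
            [
                {"child_id": "a", "household_id": 1, "genotype": "CC"},
                {"child_id": "b", "household_id": 1, "genotype": "AA"},
            ],
            [
                {"child_id": "a", "household_id": 1, "mother_id": "m1"},
                {"child_id": "b", "household_id": 1, "mother_id": "m1"},
            ],
        )
        assert pd.isna(lab["a"]) and lab["b"] == "AA"

    def test_idempotent(self, small_children):
        again = assign_slc(small_children)
        lhs = small_children["slc_label"].fillna("NA")
        rhs = again["slc_label"].fillna("NA")
        assert (lhs == rhs).all()

    def test_removing_untested_child_changes_no_other_label(self):
        roster = [
            {"child_id": "a", "household_id": 1, "genotype": "SS"},
            {"child_id": "b", "household_id": 2, "genotype": "AS"},
        ]
        bh = [
            {"child_id": "a", "household_id": 1, "mother_id": "m1"},
            {"child_id": "u1", "household_id": 1, "mother_id": "m1"},
            {"child_id": "b", "household_id": 2, "mother_id": "m2"},
            {"child_id": "u2", "household_id": 2, "mother_id": "m2"},
        ]
        full = self._label(roster, bh)
        reduced = self._label(roster, [r for r in bh if r["child_id"] != "u1"])
        for cid in ("a", "b", "u2"):
            assert full[cid] == reduced[cid]


class TestCohortFilter:
    def test_presets_and_boundaries(self, small_children):
        older = cohort_filter(small_children, "older")
        assert (older["birth_offset_months"] >= 60).all()
        assert (older["birth_offset_months"] < 180).all()
        df = pd.DataFrame({"birth_offset_months": [59, 60, 72, 179, 180]})
        assert cohort_filter(df, "older")["birth_offset_months"].tolist() == [60, 72, 179]

    def test_inverted_window_errors(self, small_children):
        with pytest.raises(ValueError):
            cohort_filter(small_children, (60, 60))
        with pytest.raises(ValueError):
            cohort_filter(small_children, "toddlers")


def test_add_under5_death():
    df = pd.DataFrame(
        {
            "alive": [True, False, False],
            "age_at_death_months": [np.nan, 30.0, 70.0],
        }
    )
    out = add_under5_death(df)
    assert out["died_u5"].tolist() == [0, 1, 0]


def test_older_cohort_slc_shares_near_survey_split(full_children):
    """Weighted SLC shares on Nigeria-like data fall near 1.6/24.8/73.6%."""
    older = cohort_filter(full_children, "older").dropna(subset=["slc_label", "weight"])
    w = older.groupby("slc_label")["weight"].sum()
    shares = 100 * w / w.sum()
    assert 0.8 <= shares["SCD"] <= 2.4
    assert 12.4 <= shares["Trait"] <= 37.2
    assert 36.8 <= shares["AA"] <= 110.4
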
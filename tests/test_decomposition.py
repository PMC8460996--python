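"""Composition matrix, the 2x2 genotype-mortality solve and burden shares."""

import numpy as np
import pandas as pd
import pytest

from scdmort.decomposition import (
    CompositionMatrix,
    _sibling_class_matrix,
    attributable_burden,
    bootstrap_gamma,
    composition_matrix,
    scd_population_shares,
    solve_genotype_mortality,
)
from scdmort.genotype_model import PARENT_PAIRS
from scdmort import sibling_linkage

from conftest import make_birth_history, make_roster

#: point values of the composition matrix as estimated on the 2018 survey
SURVEY_M = pd.DataFrame(
    [[0.893, 0.104, 0.0033], [0.447, 0.524, 0.029], [0.221, 0.499, 0.281]],
    index=["AA", "Trait", "SCD"],
    columns=["AA", "Trait", "SCD"],
)
SURVEY_M = SURVEY_M.div(SURVEY_M.sum(axis=1), axis=0)
SURVEY_WEIGHTS = pd.Series({"AA": 73.6, "Trait": 24.8, "SCD": 1.6})


def _labeled_children(roster_rows, bh_rows):
    ch = sibling_linkage.link_siblings(
        make_roster(roster_rows), make_birth_history(bh_rows)
    )
    ch = sibling_linkage.assign_slc(ch)
    return sibling_linkage.add_under5_death(ch)


class TestCompositionMatrix:
    def test_all_tested_gives_observed_proportions(self):
        # three fully tested singleton groups per SLC in the older cohort is
        # impossible (tested children are young), so test via the class-prob
        # point-mass property on the tested cohort window instead
        roster = [
            {"child_id": "a", "household_id": 1, "genotype": "AA"},
            {"child_id": "b", "household_id": 2, "genotype": "AS"},
            {"child_id": "c", "household_id": 3, "genotype": "SS"},
        ]
        bh = [
            {"child_id": "a", "household_id": 1, "mother_id": "m1",
             "birth_offset_months": 24},
            {"child_id": "b", "household_id": 2, "mother_id": "m2",
             "birth_offset_months": 24},
            {"child_id": "c", "household_id": 3, "mother_id": "m3",
             "birth_offset_months": 24},
        ]
        ch = _labeled_children(roster, bh)
        m = composition_matrix(ch, cohort="tested")
        np.testing.assert_allclose(m.matrix.to_numpy(), np.eye(3), atol=1e-12)

    def test_untested_sibling_of_as_as_posterior(self):
        """A parent pair known to be AS x AS yields the (1/4, 1/2, 1/4) row."""
        prior = np.zeros(len(PARENT_PAIRS))
        prior[PARENT_PAIRS.index(("AS", "AS"))] = 1.0
        lik = np.ones((1, len(PARENT_PAIRS)))
        row = _sibling_class_matrix(prior, lik)[0]
        np.testing.assert_allclose(row, [0.25, 0.5, 0.25], atol=1e-12)

    def test_empty_slc_errors(self):
        roster = [{"child_id": "a", "household_id": 1, "genotype": "AA"}]
        bh = [{"child_id": "a", "household_id": 1, "mother_id": "m1",
               "birth_offset_months": 70}]
        ch = _labeled_children(roster, bh)
        with pytest.raises(ValueError, match="no weighted members"):
            composition_matrix(ch, cohort="km")

    def test_full_survey_matrix_is_sensible(self, full_children):
        m = composition_matrix(full_children)
        assert np.allclose(m.matrix.sum(axis=1), 1.0)
        # diagonal dominance pattern: each SLC is enriched for its own class
        assert m.matrix.loc["AA", "AA"] > 0.8
        assert m.matrix.loc["SCD", "SCD"] > m.matrix.loc["Trait", "SCD"] > m.matrix.loc["AA", "SCD"]


class TestScdPopulationShares:
    def test_survey_arithmetic(self):
        shares = scd_population_shares(SURVEY_M, SURVEY_WEIGHTS)
        assert 100 * shares["AA"] == pytest.approx(17.2, abs=0.5)
        assert shares.sum() == pytest.approx(1.0, abs=1e-12)

    def test_concentrated_and_symmetric(self):
        m = pd.DataFrame(
            [[1.0, 0.0, 0.0], [0.5, 0.5, 0.0], [0.4, 0.3, 0.3]],
            index=["AA", "Trait", "SCD"],
            columns=["AA", "Trait", "SCD"],
        )
        w = pd.Series({"AA": 1.0, "Trait": 1.0, "SCD": 1.0})
        shares = scd_population_shares(m, w)
        assert shares["SCD"] == pytest.approx(1.0)
        m2 = m.copy()
        m2["SCD"] = [0.2, 0.2, 0.2]
        m2["AA"] = [0.5, 0.5, 0.5]
        m2["Trait"] = [0.3, 0.3, 0.3]
        np.testing.assert_allclose(scd_population_shares(m2, w), [1 / 3] * 3)


class TestSolve:
    @staticmethod
    def _cm(matrix):
        return CompositionMatrix(
            matrix=matrix, row_weights=pd.Series({"AA": 1.0, "Trait": 1.0, "SCD": 1.0})
        )

    def test_zero_beta_zero_gamma(self):
        res = solve_genotype_mortality(
            pd.Series({"Trait": 0.0, "SCD": 0.0}), self._cm(SURVEY_M)
        )
        np.testing.assert_allclose(res.gamma, 0.0, atol=1e-12)

    def test_identity_composition_returns_beta(self):
        eye = pd.DataFrame(
            np.eye(3), index=["AA", "Trait", "SCD"], columns=["AA", "Trait", "SCD"]
        )
        res = solve_genotype_mortality(
            pd.Series({"Trait": 9.0, "SCD": 99.0}), self._cm(eye)
        )
        assert res.gamma["Trait"] == pytest.approx(9.0)
        assert res.gamma["SCD"] == pytest.approx(99.0)

    def test_survey_point_solve(self):
        """Survey point values and beta=(9, 99) give gamma_scd near 357."""
        res = solve_genotype_mortality(
            pd.Series({"Trait": 9.0, "SCD": 99.0}), self._cm(SURVEY_M)
        )
        assert res.gamma["SCD"] == pytest.approx(357.0, abs=3.0)
        assert res.gamma["Trait"] == pytest.approx(-0.4, abs=1.0)

    def test_round_trip_identity(self):
        """beta built as D gamma is recovered to machine precision."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            m = rng.dirichlet((5, 3, 1), size=3)
            cm = self._cm(
                pd.DataFrame(m, index=["AA", "Trait", "SCD"],
                             columns=["AA", "Trait", "SCD"])
            )
            d = cm.difference_system()
            if abs(np.linalg.det(d)) < 1e-6:
                continue
            gamma_true = rng.normal(0, 200, 2)
            beta = d @ gamma_true
            res = solve_genotype_mortality(
                pd.Series({"Trait": beta[0], "SCD": beta[1]}), cm
            )
            np.testing.assert_allclose(res.gamma, gamma_true, rtol=1e-10)

    def test_singular_system_raises(self):
        flat = pd.DataFrame(
            np.tile([0.6, 0.3, 0.1], (3, 1)),
            index=["AA", "Trait", "SCD"],
            columns=["AA", "Trait", "SCD"],
        )
        with pytest.raises(np.linalg.LinAlgError):
            solve_genotype_mortality(
                pd.Series({"Trait": 1.0, "SCD": 2.0}), self._cm(flat)
            )

    def test_baseline_recovery(self):
        res = solve_genotype_mortality(
            pd.Series({"Trait": 9.0, "SCD": 99.0}),
            self._cm(SURVEY_M),
            m_aa_slc_crude=128.0,
        )
        expected_m_aa = 128.0 - SURVEY_M.loc["AA", "Trait"] * res.gamma["Trait"] \
            - SURVEY_M.loc["AA", "SCD"] * res.gamma["SCD"]
        assert res.m_aa == pytest.approx(expected_m_aa)
        assert res.m_scd == pytest.approx(res.m_aa + res.gamma["SCD"])


class TestAttributableBurden:
    def test_survey_arithmetic(self):
        total = attributable_burden(0.0145, 370.0, 490.0, 127.0)
        assert total.total_share_pct == pytest.approx(5.6, abs=0.1)
        assert total.excess_share_pct == pytest.approx(4.2, abs=0.1)

    def test_zero_prevalence(self):
        b = attributable_burden(0.0, 370.0, 490.0, 127.0)
        assert b.total_share_pct == 0.0 and b.excess_share_pct == 0.0

    def test_absolute_deaths_and_errors(self):
        b = attributable_burden(0.0145, 370.0, 490.0, 127.0, annual_deaths=830_000)
        assert b.annual_excess_deaths == pytest.approx(
            830_000 * b.excess_share_pct / 100.0
        )
        with pytest.raises(ValueError):
            attributable_burden(0.0145, 370.0, 490.0, 0.0)


class TestBootstrapGamma:
    def test_deterministic_given_seed(self, small_children):
        a = bootstrap_gamma(small_children, n_reps=30, seed=9)
        b = bootstrap_gamma(small_children, n_reps=30, seed=9)
        pd.testing.assert_frame_equal(a.replicates, b.replicates)
        assert a.point.gamma["SCD"] == b.point.gamma["SCD"]

    def test_duplicated_cluster_degenerate_ci(self):
        """Identical clusters make every replicate identical: CI width 0."""
        roster, bh = [], []
        for c in range(4):  # four copies of the same cluster
            for fam, genos in enumerate([("AA", "AA"), ("AS", "AA"), ("SS", "AS")]):
                hh = c * 10 + fam
                mid = f"m{hh}"
                for i, g in enumerate(genos):
                    cid = f"t{hh}-{i}"
                    roster.append(
                        {"child_id": cid, "household_id": hh, "cluster_id": c,
                         "stratum_id": 0, "genotype": g, "urban": 0,
                         "age_months": 20 + i}
                    )
                    bh.append({"child_id": cid, "household_id": hh,
                               "mother_id": mid, "birth_offset_months": 20 + i})
                # two older siblings per family, one died
                for j, died in enumerate((True, False)):
                    bh.append(
                        {"child_id": f"u{hh}-{j}", "household_id": hh,
                         "mother_id": mid, "birth_offset_months": 80 + j,
                         "alive": not died,
                         "age_at_death_months": 24.0 if died else np.nan}
                    )
        ch = _labeled_children(roster, bh)
        res = bootstrap_gamma(ch, n_reps=25, seed=3)
        lo, hi = res.ci("gamma_SCD")
        assert hi - lo == pytest.approx(0.0, abs=1e-9)

    def test_full_survey_recovery_sane(self, full_children):
        """Point estimate on one full survey lands in a broad truth band."""
        res = bootstrap_gamma(full_children, n_reps=100, seed=5)
        assert 100 <= res.point.gamma["SCD"] <= 700
        lo, hi = res.ci("gamma_SCD")
        assert lo < res.point.gamma["SCD"] < hi
        assert res.n_dropped <= 10
        assert res.point.condition_number < 100
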
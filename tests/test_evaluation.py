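"""Outcome adjudication, matching rates, chi-square and Mann-Whitney."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from noduletrack.cohort import cohort_outcome_counts, cohort_outcome_records
from noduletrack.evaluation import (
    chi2_independence,
    classify_outcomes,
    compute_rates,
    followup_detected_ids,
    mann_whitney_u,
    stratify,
)
from noduletrack.types import (
    DegenerateTableError,
    InconsistentMatchError,
    MatchResult,
    OutcomeRecord,
)

from conftest import make_record


def _match(pairs, unmatched_b=(), unmatched_f=(), thr=15.0):
    return MatchResult(list(pairs), list(unmatched_b), list(unmatched_f), thr)


class TestClassifyOutcomes:
    def setup_method(self):
        self.baseline = [
            make_record("b_fp", [0, 0, 0], true_lesion_id=None),
            make_record("b_missed", [20, 0, 0], true_lesion_id="n1"),
            make_record("b_wrong", [40, 0, 0], true_lesion_id="n7"),
            make_record("b_ok", [60, 0, 0], true_lesion_id="n3"),
            make_record("b_gone", [80, 0, 0], true_lesion_id="n5"),
        ]
        self.followup = [
            make_record("f_n9", [41, 0, 0], exam_id="fu", true_lesion_id="n9"),
            make_record("f_n3", [61, 0, 0], exam_id="fu", true_lesion_id="n3"),
        ]
        self.links = {"n1": "n1", "n7": "n7", "n3": "n3", "n5": "disappeared", "n9": "n9"}
        self.matches = _match(
            [("b_wrong", "f_n9", 1.0), ("b_ok", "f_n3", 1.0)], ["b_fp", "b_missed"]
        )

    def test_taxonomy(self):
        out = classify_outcomes(self.baseline, self.followup, self.matches, self.links)
        by_id = {o.lesion_id: o.outcome for o in out}
        assert by_id == {
            "b_fp": "false_positive_detection",
            "b_missed": "missed_matching",
            "b_wrong": "incorrect_assignment",
            "b_ok": "correct_match",
        }

    def test_disappeared_excluded_before_adjudication(self):
        out = classify_outcomes(self.baseline, self.followup, self.matches, self.links)
        assert "b_gone" not in {o.lesion_id for o in out}

    def test_count_bins_attached(self):
        out = classify_outcomes(
            self.baseline,
            self.followup,
            self.matches,
            self.links,
            case_nodule_counts={"case": 60},
        )
        assert {o.case_nodule_count_bin for o in out} == {">50"}

    def test_match_referencing_unknown_followup_rejected(self):
        bad = _match([("b_ok", "f_ghost", 1.0)])
        with pytest.raises(InconsistentMatchError, match="inconsistent"):
            classify_outcomes(self.baseline, self.followup, bad, self.links)

    def test_followup_detected_ids(self):
        det = followup_detected_ids(self.baseline, self.followup, self.links)
        # only n3's counterpart is among the follow-up detections (n7, n1 are
        # undetected; n5 disappeared; the fp has no truth link)
        assert det == {"b_ok"}


class TestComputeRates:
    def test_cohort_fixture_rates(self):
        """The reference cohort counts reproduce every published rate."""
        table = compute_rates(cohort_outcome_records())
        c = cohort_outcome_counts()
        assert table.n_total == 1141 and table.n_nodules == 1105
        assert table.counts["correct_match"] == 964
        assert table.counts["missed_matching"] == 119
        assert table.counts["incorrect_assignment"] == 22
        assert round(100 * table.overall_rate, 1) == 87.2
        assert table.conditional_denominator == 986
        assert round(100 * table.conditional_rate, 1) == 97.8
        assert round(100 * table.fp_fraction, 1) == 3.2
        assert round(100 * table.missed_fraction, 1) == 10.8
        assert round(100 * table.incorrect_fraction, 1) == 2.0
        assert round(100 * table.not_matched_fraction, 1) == 12.8
        assert c["n_lesions"] == 1141

    def test_order_invariance(self, rng):
        records = cohort_outcome_records()
        perm = [records[i] for i in rng.permutation(len(records))]
        a, b = compute_rates(records), compute_rates(perm)
        assert a.counts == b.counts
        assert a.overall_rate == b.overall_rate
        assert a.by_localization.equals(b.by_localization)

    def test_outcomes_partition_selected_lesions(self):
        t = compute_rates(cohort_outcome_records())
        assert sum(t.counts.values()) == t.n_total
        assert (
            t.counts["correct_match"]
            + t.counts["missed_matching"]
            + t.counts["incorrect_assignment"]
            == t.n_total - t.counts["false_positive_detection"]
        )

    def test_all_correct_toy_case(self):
        outcomes = [
            OutcomeRecord("caseA", f"l{i}", "correct_match", "parenchymal")
            for i in range(5)
        ]
        t = compute_rates(outcomes)
        assert t.per_case_rates == {"caseA": 1.0}
        assert t.overall_rate == 1.0

    def test_zero_denominator_flagged_not_nan(self):
        outcomes = [
            OutcomeRecord("caseA", "l0", "false_positive_detection", "parenchymal")
        ]
        t = compute_rates(outcomes)
        assert t.overall_rate is None
        assert "overall_rate" in t.undefined_rates
        assert not any(
            isinstance(v, float) and math.isnan(v)
            for v in (t.overall_rate, t.missed_fraction)
            if v is not None
        )

    def test_explicit_conditional_denominator(self):
        outcomes = [
            OutcomeRecord("c", "l0", "correct_match", "parenchymal"),
            OutcomeRecord("c", "l1", "missed_matching", "parenchymal"),
        ]
        t = compute_rates(outcomes, followup_detected={"l0", "l1"})
        assert t.conditional_rate == 0.5  # missed one was detected but unlinked


class TestChi2:
    def test_uniform_table_is_null(self):
        res = chi2_independence([[10, 10], [10, 10]])
        assert res.chi2 == 0 and res.p_value == 1
        assert np.allclose(res.pearson_residuals.to_numpy(), 0)

    @pytest.mark.filterwarnings("ignore:chi-square approximation")
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_closed_form_oracle(self, seed):
        rng = np.random.default_rng(seed)
        obs = rng.integers(1, 21, size=(3, 2)).astype(float)
        res = chi2_independence(obs)
        row = obs.sum(1, keepdims=True)
        col = obs.sum(0, keepdims=True)
        expected = row @ col / obs.sum()
        chi2_hand = ((obs - expected) ** 2 / expected).sum()
        assert abs(res.chi2 - chi2_hand) < 1e-10
        assert res.dof == 2

    def test_squared_residuals_sum_to_chi2(self, rng):
        obs = rng.integers(1, 50, size=(4, 3)).astype(float)
        res = chi2_independence(obs)
        assert abs((res.pearson_residuals.to_numpy() ** 2).sum() - res.chi2) < 1e-9

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateTableError, match="degenerate"):
            chi2_independence([[0, 0], [5, 3]])

    def test_low_expected_counts_warn(self):
        with pytest.warns(UserWarning, match="expected cell"):
            chi2_independence([[1, 2], [2, 1]])


def exact_mwu_oracle(a, b):
    """Exhaustive enumeration of the Mann-Whitney null: every assignment of
    the pooled ranks to group a, two-sided p as the tail mass of U."""
    pooled = list(a) + list(b)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    na = len(a)
    u_obs = sum(ranks[v] for v in a) - na * (na + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), na):
        r = sum(sorted(ranks.values())[i] for i in combo)
        us.append(r - na * (na + 1) / 2)
    us = np.asarray(us)
    mean_u = len(a) * len(b) / 2
    dev = abs(u_obs - mean_u)
    p = np.mean(np.abs(us - mean_u) >= dev - 1e-12)
    return u_obs, min(1.0, float(p))


class TestMannWhitney:
    def test_identical_groups_no_separation(self):
        a = [0.8, 0.9, 1.0, 0.7]
        _, p = mann_whitney_u(a, list(a))
        assert p >= 0.99

    def test_complete_separation_exact(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert abs(p - 0.1) < 1e-12  # 2/20 arrangements as extreme

    @pytest.mark.parametrize("na,nb", [(2, 3), (3, 3), (4, 5), (5, 5), (6, 4)])
    def test_exact_mode_matches_enumeration_oracle(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        a = list(rng.normal(0, 1, na))
        b = list(rng.normal(0.8, 1, nb))
        u_impl, p_impl = mann_whitney_u(a, b, mode="exact")
        u_oracle, p_oracle = exact_mwu_oracle(a, b)
        assert u_impl == u_oracle
        assert abs(p_impl - p_oracle) < 1e-9

    def test_asymptotic_close_to_exact_n8(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            a = list(rng.normal(0, 1, 8))
            b = list(rng.normal(0.5, 1, 8))
            _, p_ex = mann_whitney_u(a, b, mode="exact")
            _, p_as = mann_whitney_u(a, b, mode="asymptotic")
            assert abs(p_ex - p_as) <= 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty group"):
            mann_whitney_u([], [1.0])


class TestStratify:
    def test_cohort_localization_rates_and_table(self):
        strat = stratify(cohort_outcome_records(), "localization")
        expected = {
            "parenchymal": 91.8,
            "peripheral": 84.4,
            "juxtavascular": 82.4,
            "juxtaphrenic": 71.1,
        }
        for loc, rate in expected.items():
            assert round(100 * strat.rates[loc], 1) == rate
        assert strat.binary.loc["parenchymal"].tolist() == [504, 45]
        assert strat.binary.loc["juxtaphrenic"].tolist() == [32, 13]
        assert strat.binary_result.p_value < 0.001

    def test_all_correct_strata_degenerate_but_rates_defined(self):
        outcomes = [
            OutcomeRecord("c", f"l{i}", "correct_match", loc)
            for i, loc in enumerate(
                ["parenchymal", "peripheral", "juxtavascular", "juxtaphrenic"]
            )
        ]
        strat = stratify(outcomes, "localization")
        assert (strat.rates == 1.0).all()
        assert strat.binary_result is None  # zero incorrect margin: no chi2

    def test_dropout_concentrated_in_high_count_cases_shows_missed_residual(self):
        """Detection dropout concentrated in crowded exams leaves a positive
        missed-matching Pearson residual in the >50 stratum."""
        from noduletrack.pipeline import evaluate_study
        from noduletrack.synthetic import generate_study

        from conftest import clean_config

        cfg = clean_config(
            n_cases=30, dropout_prob=0.02, dropout_count_coupling=0.006,
            nodules_per_case={"kind": "cohort"}, min_separation_mm=10.0,
        )
        res = evaluate_study(generate_study(cfg))
        strat = res.stratified("count_bin")
        resid = strat.root_cause_result.pearson_residuals
        assert resid.loc[">50", "missed_matching"] > 0
        assert resid.loc[">50", "missed_matching"] > resid.loc["<20", "missed_matching"]

    def test_unknown_stratum_rejected(self):
        with pytest.raises(ValueError, match="invalid stratum"):
            stratify(cohort_outcome_records(), "texture")

    def test_missing_count_bins_rejected(self):
        with pytest.raises(ValueError, match="invalid stratum"):
            stratify(cohort_outcome_records(), "count_bin")

    def test_tidy_export_shape(self):
        strat = stratify(cohort_outcome_records(), "localization")
        tidy = strat.tidy()
        assert set(tidy.columns) == {
            "table", "row", "col", "observed", "expected", "residual"
        }
        binary = tidy[tidy["table"] == "binary"]
        assert len(binary) == 8  # 4 strata x {correct, incorrect}
        assert np.isclose(
            (binary["residual"] ** 2).sum(), strat.binary_result.chi2
        )
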
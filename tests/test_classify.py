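"""Phenotype classification: profiles, decision rules, grading, census, LR validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vlpoca import (
    ClassifierThresholds,
    Hypnogram,
    census_percentages,
    classify_call,
    classify_units,
    grade_strength,
    logistic_validation,
    state_activity_profiles,
    tabulate_census,
)
from vlpoca.classify import SUBTYPE_COLUMNS
from vlpoca.datasets import REFERENCE_GROUP_MEANS


def call_from_means(m_aw, m_qw, m_nrem, m_rem):
    return classify_call(m_nrem / m_aw, m_rem / m_aw, m_rem / m_nrem)


class TestProfiles:
    def test_constant_unit_has_unit_ratios(self):
        hyp = Hypnogram(states=np.array(["AW", "QW", "NREM", "REM"], dtype=object))
        em = pd.DataFrame({"u": [1.0, 1.0, 1.0, 1.0]})
        prof = state_activity_profiles(em, hyp)
        row = prof.loc["u"]
        assert all(row[f"m_{s}"] == 1.0 for s in ("AW", "QW", "NREM", "REM"))
        assert row["r_NA"] == row["r_RA"] == row["r_RN"] == 1.0

    def test_means_and_ratios_arithmetic(self):
        hyp = Hypnogram(states=np.array(["AW", "AW", "NREM", "REM"], dtype=object))
        em = pd.DataFrame({"u": [1.0, 3.0, 4.0, 2.0]})
        row = state_activity_profiles(em, hyp).loc["u"]
        assert (row["m_AW"], row["m_NREM"], row["m_REM"]) == (2.0, 4.0, 2.0)
        assert (row["r_NA"], row["r_RA"], row["r_RN"]) == (2.0, 1.0, 0.5)

    def test_missing_state_gives_undefined_ratios_and_unclassifiable(self):
        hyp = Hypnogram(states=np.array(["AW", "NREM"], dtype=object))
        em = pd.DataFrame({"u": [1.0, 2.0]})
        prof = state_activity_profiles(em, hyp)
        assert np.isnan(prof.loc["u", "r_RA"])
        calls = classify_units(prof)
        assert calls.loc["u", "category"] == "unclassifiable"


class TestDecisionRules:
    @pytest.mark.parametrize("example", REFERENCE_GROUP_MEANS, ids=lambda e: e["subtype"])
    def test_reported_group_means_map_to_their_subtype(self, example):
        _, subtype = call_from_means(
            example["AW"], example["QW"], example["NREM"], example["REM"]
        )
        assert subtype == example["subtype"]

    def test_equal_means_are_state_indifferent(self):
        assert call_from_means(1.0, 1.0, 1.0, 1.0) == ("state-indifferent", "none")

    def test_rem_rule_precedes_nonrem_rule(self):
        # elevated NREM/AW (1.8) but REM ratios > 2 -> REM-active, not nonREM
        cat, sub = classify_call(1.8, 5.78, 3.21)
        assert (cat, sub) == ("sleep-active", "REMS-active")

    def test_wake_subtype_boundaries_are_strict(self):
        # r_RA exactly at either cut falls to wake-max
        assert classify_call(0.5, 0.75, 1.5)[1] == "wake-max"
        assert classify_call(0.5, 2.0, 4.0)[1] == "wake-max"
        assert classify_call(0.5, 1.0, 2.0)[1] == "wake/REMS-max"

    def test_undefined_ratio_is_unclassifiable(self):
        assert classify_call(np.nan, 1.0, 1.0) == ("unclassifiable", "none")

    @settings(derandomize=True, max_examples=100)
    @given(
        m=st.tuples(*[st.floats(0.05, 5.0) for _ in range(4)]),
        c=st.floats(0.01, 100.0),
    )
    def test_scale_invariance(self, m, c):
        a = call_from_means(*m)
        b = call_from_means(*(c * x for x in m))
        assert a == b

    def test_agrees_with_truth_table_oracle(self):
        """Decision-order classifier vs an exhaustive rule-set evaluation."""
        t = ClassifierThresholds()

        def oracle(r_na, r_ra, r_rn):
            rems = r_ra > t.rem_cut and r_rn > t.rem_cut
            nrem = r_na > t.sleep_cut
            wake = r_na < t.wake_cut
            table = {
                (True, False, False): ("sleep-active", "REMS-active"),
                (True, True, False): ("sleep-active", "REMS-active"),
                (True, False, True): ("sleep-active", "REMS-active"),
                (True, True, True): ("sleep-active", "REMS-active"),
                (False, True, False): (
                    "sleep-active",
                    "nonREMS/REMS-max" if r_rn > t.rem_retention_cut else "nonREMS-max",
                ),
                (False, False, True): (
                    "wake-active",
                    "wake/REMS-max" if t.wake_cut < r_ra < t.rem_cut else "wake-max",
                ),
                (False, False, False): ("state-indifferent", "none"),
            }
            return table[(rems, nrem, wake)]

        rng = np.random.default_rng(7)
        r_na = np.exp(rng.normal(0, 0.8, 10_000))
        r_ra = np.exp(rng.normal(0, 0.8, 10_000))
        r_rn = r_ra / r_na
        for a, b, c in zip(r_na, r_ra, r_rn):
            assert classify_call(a, b, c) == oracle(a, b, c)


class TestGrading:
    def test_sleep_active_bands(self):
        assert grade_strength(1.0, 1.4, 1.0, "sleep-active", "nonREMS-max")[0] == "weak"
        assert grade_strength(1.0, 1.8, 1.2, "sleep-active", "nonREMS/REMS-max")[0] == "moderate"
        assert grade_strength(1.0, 2.5, 2.6, "sleep-active", "nonREMS/REMS-max")[0] == "strong"

    def test_rems_active_uses_smaller_rem_fold(self):
        # REM/AW = 4, REM/NREM = 1.6 -> e = 0.6 -> moderate
        grade, flagged = grade_strength(0.5, 1.25, 2.0, "sleep-active", "REMS-active")
        assert (grade, flagged) == ("moderate", False)

    def test_wake_max_uses_smaller_decline_fold(self):
        # min(AW/NREM, AW/REM) = min(2.5, 2.22) -> e = 1.22 -> strong
        grade, flagged = grade_strength(2.0, 0.8, 0.9, "wake-active", "wake-max")
        assert (grade, flagged) == ("strong", False)

    def test_state_indifferent_has_no_grade(self):
        assert grade_strength(1.0, 1.0, 1.0, "state-indifferent", "none") == ("none", False)

    def test_sub_band_effect_is_flagged(self):
        # wake-max with REM fold below the 25% band (r_RA exactly 2.0 case)
        grade, flagged = grade_strength(1.0, 0.5, 2.0, "wake-active", "wake-max")
        assert grade == "none" and flagged


class TestCensus:
    def make_calls(self):
        rows = []
        for i, sub in enumerate(SUBTYPE_COLUMNS):
            for j in range(i + 1):  # 1, 2, ..., 6 units per subtype
                cat = (
                    "state-indifferent"
                    if sub == "state-indifferent"
                    else ("wake-active" if "wake" in sub else "sleep-active")
                )
                rows.append(
                    {
                        "unit_id": f"u{len(rows)}",
                        "category": cat,
                        "subtype": "none" if cat == "state-indifferent" else sub,
                        "grade": "none",
                        "flagged": False,
                        "animal_id": f"m{j % 2}",
                        "genotype": "VGAT",
                    }
                )
        return pd.DataFrame(rows).set_index("unit_id")

    def test_row_counts_sum_to_totals(self):
        census = tabulate_census(self.make_calls())
        sums = census[list(SUBTYPE_COLUMNS)].sum(axis=1)
        assert (sums == census["total"]).all()
        assert census["total"].sum() == 21

    def test_empty_calls_yield_empty_table(self):
        census = tabulate_census(pd.DataFrame())
        assert census.empty

    def test_percentage_arithmetic_on_constructed_counts(self):
        counts = dict(zip(SUBTYPE_COLUMNS, [30, 10, 20, 25, 5, 10]))
        table = census_percentages(counts).set_index("metric")
        assert table.loc["sleep_active_of_total", "pct"] == 60  # 60/100
        assert table.loc["wake_active_of_total", "pct"] == 30
        assert table.loc["nonrem_rem_max_of_nonrem", "pct"] == 75  # 30/40


class TestLogisticValidation:
    def make_profiles(self, n=200, seed=3):
        rng = np.random.default_rng(seed)
        member = rng.random(n) < 0.4
        r_na = np.where(
            member, rng.normal(0.4, 0.15, n), rng.normal(1.6, 0.5, n)
        ).clip(0.01)
        return pd.DataFrame({"r_NA": r_na}), member

    def test_wake_rule_has_negative_significant_coefficient(self):
        prof, member = self.make_profiles()
        res = logistic_validation(prof, member, "wake-active")
        assert res.coef[0] < 0
        assert res.pvalues[0] < 0.05
        assert not res.separation

    def test_agrees_with_independent_newton_solver(self):
        prof, member = self.make_profiles()

        def newton_logit(X, y, iters=100):
            X = np.column_stack([np.ones(len(X)), X])
            beta = np.zeros(X.shape[1])
            for _ in range(iters):
                eta = X @ beta
                p = 1 / (1 + np.exp(-eta))
                W = p * (1 - p)
                H = X.T @ (X * W[:, None])
                g = X.T @ (y - p)
                beta = beta + np.linalg.solve(H, g)
            return beta

        res = logistic_validation(prof, member, "wake-active")
        beta = newton_logit(prof[["r_NA"]].to_numpy(), member.astype(float))
        assert res.intercept == pytest.approx(beta[0], abs=1e-5)
        assert res.coef[0] == pytest.approx(beta[1], abs=1e-5)

    def test_permuted_labels_give_null_like_pvalues(self):
        prof, member = self.make_profiles(n=200, seed=11)
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(100):
            res = logistic_validation(prof, rng.permutation(member), "wake-active")
            pvals.append(res.pvalues[0])
        pvals = np.asarray(pvals)
        assert 0.3 < pvals.mean() < 0.7
        assert np.mean(pvals < 0.05) <= 0.12

    def test_perfect_separation_is_flagged(self):
        prof = pd.DataFrame({"r_NA": np.r_[np.full(20, 0.3), np.full(20, 2.0)]})
        res = logistic_validation(prof, prof["r_NA"] < 1.0, "wake-active")
        assert res.separation

    def test_single_class_outcome_rejected(self):
        prof = pd.DataFrame({"r_NA": [0.5, 0.6, 0.7]})
        with pytest.raises(ValueError, match="single class"):
            logistic_validation(prof, [True, True, True], "wake-active")

    def test_joint_fit_for_two_ratio_rules(self):
        rng = np.random.default_rng(5)
        n = 300
        member = rng.random(n) < 0.3
        r_ra = np.where(member, rng.normal(3.0, 0.6, n), rng.normal(1.0, 0.4, n)).clip(0.01)
        r_rn = np.where(member, rng.normal(3.0, 0.6, n), rng.normal(0.9, 0.4, n)).clip(0.01)
        prof = pd.DataFrame({"r_RA": r_ra, "r_RN": r_rn})
        res = logistic_validation(prof, member, "REMS-active")
        assert res.predictors == ["r_RA", "r_RN"]
        assert len(res.coef) == 2
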
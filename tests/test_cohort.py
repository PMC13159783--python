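"""ASQ-3 scoring rules, group tests, categorical dispatch, and odds ratios."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neomat.cohort import (
    ASQRecord,
    apply_inclusion_criteria,
    build_table1,
    categorical_assoc,
    compare_delta_by_factor,
    logistic_or,
    score_asq,
)
from neomat.synthetic import ASQ_DOMAINS, CohortGenConfig, InfantRecord, generate_cohort

from .oracles import ranksum_exact_p


def make_record(responses_by_domain, age_months=24.0):
    responses = {d: ["yes"] * 6 for d in ASQ_DOMAINS}
    responses.update(responses_by_domain)
    return ASQRecord(patient_id="A1", age_months=age_months, responses=responses)


class TestScoreASQ:
    def test_all_yes_domain_scores_maximum(self):
        rec = score_asq(make_record({}))
        assert all(v == 60.0 for v in rec.domain_scores.values())
        assert rec.total_score == 300.0
        assert rec.total_abnormal is False

    def test_thresholds_35_communication_25_others(self):
        items30 = ["yes"] * 3 + ["not_yet"] * 3  # domain score 30
        rec = score_asq(make_record({"communication": items30,
                                     "personal_social": items30}))
        assert rec.domain_abnormal["communication"] is True  # 30 < 35
        assert rec.domain_abnormal["personal_social"] is False  # 30 >= 25

    def test_boundary_scores_classify_exactly(self):
        at35 = ["yes"] * 3 + ["sometimes"] * 1 + ["not_yet"] * 2  # = 35
        rec = score_asq(make_record({"communication": at35}))
        assert rec.domain_abnormal["communication"] is False  # abnormal iff < 35

    def test_total_boundary_220(self):
        # four full domains (240) minus one at 0 gives 240; craft exactly 220
        items40 = ["yes"] * 4 + ["not_yet"] * 2
        rec = score_asq(
            make_record(
                {
                    "communication": items40,  # 40
                    "gross_motor": items40,  # 40
                    "fine_motor": items40,  # 40
                    "problem_solving": items40,  # 40
                    "personal_social": ["yes"] * 6,  # 60 -> total 220
                }
            )
        )
        assert rec.total_score == 220.0
        assert rec.total_abnormal is True  # abnormal iff total <= 220

    def test_missing_item_adjustment(self):
        # five answered items summing 40, one missing -> 40/5*6 = 48
        items = ["yes", "yes", "yes", "yes", "not_yet", "missing"]
        rec = score_asq(make_record({"gross_motor": items}))
        assert rec.domain_scores["gross_motor"] == pytest.approx(48.0)

    def test_three_missing_items_undefine_domain_and_total(self):
        items = ["yes"] * 3 + ["missing"] * 3
        rec = score_asq(make_record({"fine_motor": items}))
        assert rec.domain_scores["fine_motor"] is None
        assert rec.domain_abnormal["fine_motor"] is None
        assert rec.total_score is None and rec.total_abnormal is None

    def test_adjustment_equals_raw_when_complete(self):
        items = ["yes", "sometimes", "yes", "not_yet", "sometimes", "yes"]
        rec = score_asq(make_record({"communication": items}))
        assert rec.domain_scores["communication"] == 40.0

    def test_age_window_flags_analyzability(self):
        assert score_asq(make_record({}, age_months=24.0)).analyzable
        assert not score_asq(make_record({}, age_months=27.0)).analyzable
        assert score_asq(make_record({}, age_months=21.0)).analyzable

    def test_invalid_token_rejected(self):
        with pytest.raises(ValueError, match="maybe"):
            score_asq(make_record({"communication": ["maybe"] * 6}))

    upgrade = {"not_yet": "sometimes", "sometimes": "yes", "yes": "yes"}

    @settings(derandomize=True, max_examples=40)
    @given(
        st.lists(st.sampled_from(["yes", "sometimes", "not_yet"]), min_size=6, max_size=6),
        st.integers(min_value=0, max_value=5),
    )
    def test_upgrading_an_item_never_lowers_score_or_worsens_flag(self, items, idx):
        base = score_asq(make_record({"communication": items}))
        upgraded = list(items)
        upgraded[idx] = self.upgrade[items[idx]]
        up = score_asq(make_record({"communication": upgraded}))
        assert up.domain_scores["communication"] >= base.domain_scores["communication"]
        if base.domain_abnormal["communication"] is False:
            assert up.domain_abnormal["communication"] is False


class TestCompareDeltaByFactor:
    def test_identical_groups_p_one(self):
        df = pd.DataFrame({"g": [0, 0, 0, 1, 1, 1], "delta34_weeks": [1, 2, 3, 1, 2, 3]})
        rows = compare_delta_by_factor(df, "g")
        assert rows[0].p_value == 1.0

    def test_separated_groups_exact_p_matches_enumeration(self):
        x, y = [1.0, 2.0, 3.0], [11.0, 12.0, 13.0]
        df = pd.DataFrame({"g": [0] * 3 + [1] * 3, "delta34_weeks": x + y})
        rows = compare_delta_by_factor(df, "g")
        assert rows[0].median == 2.0 and rows[1].median == 12.0
        assert rows[0].p_value == pytest.approx(ranksum_exact_p(x, y))
        assert rows[0].p_value == pytest.approx(0.1)

    def test_three_categories_dispatch_kruskal(self, rng):
        df = pd.DataFrame(
            {"g": list("abc") * 10, "delta34_weeks": rng.normal(2, 1, 30)}
        )
        assert compare_delta_by_factor(df, "g")[0].test_name == "kruskal_wallis"

    def test_parametric_flag(self, rng):
        df = pd.DataFrame({"g": [0, 1] * 15, "delta34_weeks": rng.normal(2, 1, 30)})
        assert compare_delta_by_factor(df, "g", parametric=True)[0].test_name == "student_t"

    def test_single_category_rejected(self):
        df = pd.DataFrame({"g": [1] * 5, "delta34_weeks": range(5)})
        with pytest.raises(ValueError, match="2 non-empty"):
            compare_delta_by_factor(df, "g")


class TestCategoricalAssoc:
    def test_perfect_independence_p_one(self):
        res = categorical_assoc([[10, 10], [10, 10]])
        assert res.p_value == pytest.approx(1.0, abs=1e-9)
        assert res.test_name == "chi_square"

    def test_fisher_dispatch_on_low_expected(self):
        # margins give a minimum expected count of 6*6/87 < 5
        res = categorical_assoc([[2, 4], [4, 77]])
        assert res.test_name == "fisher_exact"
        assert res.min_expected < 5

    def test_larger_table_with_healthy_margins_uses_chi_square(self):
        res = categorical_assoc([[10, 20], [20, 10], [15, 15]])
        assert res.test_name == "chi_square"

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            categorical_assoc([[0, 0], [5, 5]])


class TestLogisticOr:
    def test_saturated_2x2_equals_cross_product_ratio(self):
        # exposed: 2 events / 6; unexposed: 4 events / 81
        y = [1] * 2 + [0] * 4 + [1] * 4 + [0] * 77
        x = [1] * 6 + [0] * 81
        res = logistic_or(pd.DataFrame({"y": y, "x": x}), "y", "x")
        assert res.odds_ratio == pytest.approx((2 * 77) / (4 * 4), abs=1e-3)

    def test_null_predictor_or_near_one(self, rng):
        df = pd.DataFrame(
            {"y": rng.random(20000) < 0.3, "x": rng.normal(0, 1, 20000)}
        ).astype({"y": float})
        res = logistic_or(df, "y", "x")
        assert 0.9 <= res.odds_ratio <= 1.1

    def test_single_class_outcome_rejected(self):
        df = pd.DataFrame({"y": [0.0] * 10, "x": range(10)})
        with pytest.raises(ValueError, match="binary"):
            logistic_or(df, "y", "x")

    def test_complete_separation_flagged(self):
        df = pd.DataFrame({"y": [0] * 10 + [1] * 10, "x": list(range(10)) + list(range(20, 30))})
        res = logistic_or(df.astype(float), "y", "x")
        assert res.separation
        assert math.isinf(res.odds_ratio)


class TestInclusionFlow:
    def _records(self):
        recs = []
        for i in range(170):
            recs.append(
                InfantRecord(
                    patient_id=f"E{i:03d}",
                    ga_weeks=27.0,
                    ga_stratum="26-<28",
                    sex="male",
                    covariates={},
                    latent_delta34=2.0,
                    followup=False,
                    has_ecg=i >= 23,
                    used_for_training=23 <= i < 38,
                )
            )
        # ASQ completed for 87 of the included 132
        included = [r for r in recs if r.has_ecg and not r.used_for_training]
        for r in included[:87]:
            r.followup = True
        return recs

    def test_flow_counts(self):
        included, flow = apply_inclusion_criteria(self._records())
        assert flow.n_eligible == 170
        assert flow.n_no_ecg == 23
        assert flow.n_model_training == 15
        assert flow.n_included == len(included) == 132
        assert flow.n_followup == 87
        assert flow.followup_percent == 66
        assert flow.included_percent == pytest.approx(77.6, abs=0.05)


class TestBuildTable1:
    def test_percent_formatting_and_sums(self):
        rng = np.random.default_rng(0)
        n = 132
        df = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "sex": ["male"] * 68 + ["female"] * 64,
                "bpd": rng.integers(0, 2, n),
                "delta34_weeks": rng.lognormal(np.log(2.3), 0.5, n),
            }
        )
        table = build_table1(df, variables=("sex", "bpd"))
        male = table[(table.variable == "sex") & (table.category == "male")]
        assert male["percent"].iloc[0] == 51.5  # 68/132 printed to 1 decimal
        for _, grp in table.groupby("variable"):
            assert grp["percent"].sum() == pytest.approx(100.0, abs=0.2)

    def test_absent_variable_warns_and_omits(self):
        df = pd.DataFrame(
            {
                "patient_id": ["a", "b", "c", "d"],
                "sex": ["male", "female", "male", "female"],
                "delta34_weeks": [1.0, 2.0, 3.0, 4.0],
            }
        )
        with pytest.warns(UserWarning, match="absent"):
            table = build_table1(df, variables=("sex", "bpd"))
        assert set(table["variable"]) == {"sex"}

    def test_full_synthetic_cohort_emits_all_blocks(self):
        from neomat.synthetic import cohort_frame

        df = cohort_frame(generate_cohort(CohortGenConfig(n_infants=132, seed=3)))
        df["delta34_weeks"] = df["latent_delta34"]
        table = build_table1(df)
        assert {"bpd", "pda", "neuro_lesions", "tobacco", "ga_stratum"} <= set(
            table["variable"]
        )
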
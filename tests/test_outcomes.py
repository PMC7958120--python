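"""Frailty classification, outcome scoring, score model, fits, cut-points."""

import itertools

import numpy as np
import pandas as pd
import pytest

from frailgait import (
    SEVERE_FRAILTY_THRESHOLD,
    SEVERITY_WEIGHTS,
    AdverseScoreModel,
    CohortConfig,
    InvalidParameterError,
    MissingFeatureError,
    OutcomeRecord,
    PREDICTORS,
    SingularDesignError,
    classify_frailty,
    compare_groups,
    cutpoint_analysis,
    fit_adverse_model,
    generate_cohort,
    outcome_score,
    predict_adverse_score,
)
from frailgait.outcomes import sens_spec_at

from oracles import cutpoint_bruteforce

ID02 = {"rms_ap": 0.093, "rms_v": 0.118, "apen_ml_cop": 0.991,
        "apen_r_cop": 1.105, "step_time": 0.550}
ID25 = {"rms_ap": 0.111, "rms_v": 0.137, "apen_ml_cop": 1.097,
        "apen_r_cop": 1.076, "step_time": 0.540}


class TestFrailtyClassification:
    @pytest.mark.parametrize(
        "speed,expected",
        [(0.67, "frail"), (0.98, "non-frail"), (0.833, "non-frail"), (0.832, "frail")],
    )
    def test_threshold_rule(self, speed, expected):
        assert classify_frailty(speed) == expected

    def test_severe_threshold(self):
        assert classify_frailty(0.6, threshold=SEVERE_FRAILTY_THRESHOLD) == "frail"
        assert classify_frailty(0.7, threshold=SEVERE_FRAILTY_THRESHOLD) == "non-frail"

    def test_nonpositive_speed_rejected(self):
        with pytest.raises(InvalidParameterError):
            classify_frailty(0.0)


class TestOutcomeScore:
    def test_death_only(self):
        assert outcome_score(OutcomeRecord(death=True)) == 7

    def test_no_events(self):
        assert outcome_score(OutcomeRecord()) == 0

    def test_stroke_plus_reoperation_by_aggregation(self):
        record = OutcomeRecord(stroke=True, reoperation=True)
        assert outcome_score(record, "sum") == 5
        assert outcome_score(record, "max") == 3

    def test_max_never_exceeds_sum(self):
        names = list(SEVERITY_WEIGHTS)
        for flags in itertools.product([False, True], repeat=len(names)):
            record = OutcomeRecord(**dict(zip(names, flags)))
            assert outcome_score(record, "max") <= outcome_score(record, "sum")


class TestAdverseScoreModel:
    def test_published_coefficients_exact(self):
        m = AdverseScoreModel.published()
        assert m.intercept == 44.13
        assert [m.coefficients[p] for p in PREDICTORS] == [-26.96, -28.29, 13.33, -46.85, 5.35]
        assert m.provenance == "published"

    def test_worked_examples(self):
        m = AdverseScoreModel.published()
        assert m.predict(ID02) == pytest.approx(2.613, abs=0.06)
        assert m.predict(ID25) == pytest.approx(4.340, abs=0.06)

    def test_zero_features_return_intercept(self):
        m = AdverseScoreModel.published()
        assert m.predict({p: 0.0 for p in PREDICTORS}) == 44.13

    def test_missing_predictor_named_in_error(self):
        m = AdverseScoreModel.published()
        row = dict(ID02)
        del row["apen_r_cop"]
        with pytest.raises(MissingFeatureError, match="apen_r_cop"):
            m.predict(row)

    def test_linearity(self, rng):
        m = AdverseScoreModel.published()
        x = {p: rng.normal() for p in PREDICTORS}
        y = {p: rng.normal() for p in PREDICTORS}
        for alpha in (0.0, 0.3, 1.0):
            blend = {p: alpha * x[p] + (1 - alpha) * y[p] for p in PREDICTORS}
            expected = alpha * m.predict(x) + (1 - alpha) * m.predict(y)
            assert m.predict(blend) == pytest.approx(expected, abs=1e-9)

    def test_text_round_trip(self, tmp_path):
        m = AdverseScoreModel.published()
        path = tmp_path / "model.txt"
        m.save(path)
        back = AdverseScoreModel.load(path)
        assert back.intercept == m.intercept and back.coefficients == m.coefficients
        assert back.provenance == "published"


class TestFit:
    def test_zero_noise_cohort_recovers_published_model(self):
        features, outcomes = generate_cohort(CohortConfig(n_subjects=16, seed=3),
                                             score_noise_sd=0.0)
        published = AdverseScoreModel.published()
        fitted = fit_adverse_model(features, outcomes["latent_score"])
        assert fitted.intercept == pytest.approx(published.intercept, abs=1e-6)
        for p in PREDICTORS:
            assert fitted.coefficients[p] == pytest.approx(published.coefficients[p], abs=1e-6)
        assert fitted.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_full_model_cp_equals_parameter_count(self):
        features, outcomes = generate_cohort(CohortConfig(n_subjects=30, seed=9),
                                             score_noise_sd=1.0)
        fitted = fit_adverse_model(features, outcomes["latent_score"])
        assert fitted.mallows_cp == pytest.approx(len(PREDICTORS) + 1)

    def test_parameter_recovery_for_arbitrary_coefficients(self, rng):
        for _ in range(5):
            X = pd.DataFrame(rng.normal(size=(20, 5)), columns=list(PREDICTORS))
            beta = rng.normal(size=6)
            y = beta[0] + X.to_numpy() @ beta[1:]
            fitted = fit_adverse_model(X, y)
            assert fitted.intercept == pytest.approx(beta[0], abs=1e-8)
            for j, p in enumerate(PREDICTORS):
                assert fitted.coefficients[p] == pytest.approx(beta[j + 1], abs=1e-8)

    def test_duplicated_column_raises_singular_with_vif_flag(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 5)), columns=list(PREDICTORS))
        X["rms_v"] = X["rms_ap"]  # perfect collinearity
        with pytest.raises(SingularDesignError) as err:
            fit_adverse_model(X, rng.normal(size=20))
        assert err.value.vif_flag

    def test_too_few_rows_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(6, 5)), columns=list(PREDICTORS))
        with pytest.raises(InvalidParameterError):
            fit_adverse_model(X, rng.normal(size=6))


class TestCompareGroups:
    def test_identical_groups(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        out = compare_groups(df, ["a"] * 3 + ["b"] * 3)
        assert out.loc["v", "p_value"] == pytest.approx(1.0)
        assert out.loc["v", "mean_a"] == out.loc["v", "mean_b"]
        assert not out.loc["v", "significant"]

    def test_toy_table_means_match_hand_oracle(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0, 10.0, 12.0, 14.0]})
        out = compare_groups(df, ["a"] * 3 + ["b"] * 3)
        assert out.loc["v", "mean_a"] == pytest.approx(2.0)
        assert out.loc["v", "sd_a"] == pytest.approx(1.0)
        assert out.loc["v", "mean_b"] == pytest.approx(12.0)
        assert out.loc["v", "sd_b"] == pytest.approx(2.0)

    def test_velocity_significant_under_cohort_moments(self):
        # groups drawn with the published morbid / non-morbid velocity moments
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(100):
            a = rng.normal(0.637, 0.064, size=50)
            b = rng.normal(0.793, 0.222, size=50)
            df = pd.DataFrame({"smartphone_velocity": np.concatenate([a, b])})
            out = compare_groups(df, ["morbid"] * 50 + ["nonmorbid"] * 50)
            hits += bool(out.loc["smartphone_velocity", "significant"])
        assert hits >= 95

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0]})
        with pytest.raises(InvalidParameterError):
            compare_groups(df, ["a", "a", "a"])


class TestCutpoints:
    def test_perfect_separation(self):
        values = [0.1, 0.2, 0.3, 0.8, 0.9, 1.0]
        labels = [1, 1, 1, 0, 0, 0]
        rule = cutpoint_analysis(values, labels, direction="<=")
        assert rule.sensitivity == 1.0 and rule.specificity == 1.0
        assert 0.3 < rule.threshold < 0.8

    @pytest.mark.parametrize("direction", ["<=", ">"])
    def test_matches_bruteforce_scan(self, direction, rng):
        for _ in range(10):
            values = rng.normal(size=10)
            labels = rng.integers(0, 2, size=10)
            if labels.all() or not labels.any():
                continue
            rule = cutpoint_analysis(values, labels, direction=direction)
            thr, sens, spec = cutpoint_bruteforce(values, labels, direction)
            assert rule.threshold == pytest.approx(thr)
            assert rule.sensitivity == pytest.approx(sens)
            assert rule.specificity == pytest.approx(spec)

    def test_reported_rates_consistent_with_confusion_matrix(self, rng):
        values = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        rule = cutpoint_analysis(values, labels, direction="<=")
        sens, spec = sens_spec_at(values, labels.astype(bool), rule.threshold, "<=")
        assert 0 <= rule.sensitivity <= 1 and 0 <= rule.specificity <= 1
        assert rule.sensitivity == sens and rule.specificity == spec

    def test_single_class_rejected(self):
        with pytest.raises(InvalidParameterError):
            cutpoint_analysis([1.0, 2.0, 3.0], [1, 1, 1])


def test_predict_adverse_score_function_matches_method():
    m = AdverseScoreModel.published()
    assert predict_adverse_score(ID02, m) == m.predict(ID02)
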
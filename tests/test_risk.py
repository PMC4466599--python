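"""Risk models: fitting, stepwise selection, calibration and metrics."""
import json
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq
from scipy.special import expit

import childcheck as cc
from conftest import brute_force_auc, brute_force_low_cutoff


class TestPredictRisk:
    def test_zero_linear_predictor_gives_half(self):
        model = cc.RiskModel("o", intercept=0.0, coefficients={"x": 1.0})
        assert model.predict({"x": 0.0}) == pytest.approx(0.5)

    def test_quarter_probability_intercept(self):
        # oracle: solve logistic(b) = 0.25 numerically
        b = brentq(lambda t: expit(t) - 0.25, -10, 10)
        model = cc.RiskModel("o", intercept=-1.0986, coefficients={})
        assert model.predict({}) == pytest.approx(expit(b), abs=1e-4)
        assert b == pytest.approx(math.log(1 / 3), abs=1e-9)

    def test_monotone_in_intercept(self):
        probs = [
            cc.RiskModel("o", intercept=b, coefficients={}).predict({})
            for b in np.linspace(-8, 8, 17)
        ]
        assert all(a < b for a, b in zip(probs, probs[1:]))
        assert all(0.0 < p < 1.0 for p in probs)

    def test_missing_covariate_named(self):
        model = cc.RiskModel("o", intercept=0.0, coefficients={"bullied": 1.0})
        with pytest.raises(cc.ValidationError, match="bullied"):
            model.predict({"victimised": 1.0})


class TestFitLogistic:
    def test_intercept_only_recovers_logit_prevalence(self):
        frame = pd.DataFrame({"y": [1] * 20 + [0] * 80})
        model = cc.fit_logistic(frame, "y")
        assert model.intercept == pytest.approx(math.log(0.25), abs=1e-6)

    def test_null_covariate_coefficient_near_zero(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame({"x": rng.normal(size=4000), "y": rng.integers(0, 2, 4000)})
        model = cc.fit_logistic(frame, "y", ["x"])
        assert abs(model.coefficients["x"]) < 0.1
        assert model.p_values["x"] > 0.01

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_known_effect_recovered_within_tolerance(self, seed):
        rng = np.random.default_rng(seed)
        n, beta = 5000, 1.0
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(-1.0 + beta * x)).astype(int)
        model = cc.fit_logistic(pd.DataFrame({"x": x, "y": y}), "y", ["x"])
        assert model.coefficients["x"] == pytest.approx(beta, abs=0.15)

    def test_perfect_separation_names_covariate(self):
        frame = pd.DataFrame({"x": [0, 1, 2, 3, 10, 11, 12, 13], "y": [0, 0, 0, 0, 1, 1, 1, 1]})
        with pytest.raises(cc.SeparationError, match="x"):
            cc.fit_logistic(frame, "y", ["x"])

    def test_single_class_outcome_rejected(self):
        frame = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [1, 1, 1]})
        with pytest.raises(cc.ValidationError):
            cc.fit_logistic(frame, "y", ["x"])

    def test_too_few_rows_rejected(self):
        frame = pd.DataFrame({"x": [1.0, 2.0], "y": [0, 1]})
        with pytest.raises(cc.ValidationError):
            cc.fit_logistic(frame, "y", ["x"])


class TestAuc:
    def test_perfect_separation_is_one(self):
        assert cc.auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_all_ties_is_half(self):
        assert cc.auc([5.0] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_worked_example_matches_pair_counting(self):
        scores, outcomes = [1, 2, 3, 4, 5, 6], [0, 0, 1, 0, 1, 1]
        expected = brute_force_auc(scores, outcomes)  # 8 of 9 pairs ordered
        assert expected == pytest.approx(8 / 9)
        assert cc.auc(scores, outcomes) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(cc.ValidationError):
            cc.auc([1, 2, 3], [0, 0, 0])

    def test_agrees_with_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = rng.integers(4, 51)
            scores = rng.choice(np.linspace(0, 1, 12), size=n)  # forces ties
            outcomes = rng.integers(0, 2, n)
            if outcomes.min() == outcomes.max():
                continue
            assert cc.auc(scores, outcomes) == pytest.approx(
                brute_force_auc(scores, outcomes), abs=1e-12
            )


class TestCalibrateHighCutoff:
    def test_ten_percent_of_thousand_distinct_scores_exceed(self):
        rng = np.random.default_rng(7)
        scores = rng.permutation(np.linspace(0.01, 0.99, 1000))
        cut = cc.calibrate_high_cutoff(scores, 0.10)
        assert int(np.sum(scores > cut)) == 100

    def test_zero_prevalence_degenerate_bound(self):
        scores = [0.2, 0.5, 0.9]
        cut = cc.calibrate_high_cutoff(scores, 0.0)
        assert cut >= max(scores)
        assert np.sum(np.asarray(scores) > cut) == 0

    def test_quarter_prevalence_on_1_to_100(self):
        scores = np.arange(1.0, 101.0)
        cut = cc.calibrate_high_cutoff(scores, 0.25)
        # oracle: brute-force scan of all candidate cut-offs
        best = min(
            (c for c in scores if np.sum(scores > c) <= 25),
            key=lambda c: abs(np.sum(scores > c) - 25),
        )
        assert cut == best
        assert int(np.sum(scores > cut)) == 25

    @given(
        n=st.integers(2, 120),
        prevalence=st.floats(0.0, 1.0),
        seed=st.integers(0, 10_000),
    )
    def test_exceed_fraction_never_overshoots(self, n, prevalence, seed):
        rng = np.random.default_rng(seed)
        scores = rng.choice(np.linspace(0, 1, 17), size=n)  # heavy ties
        cut = cc.calibrate_high_cutoff(scores, prevalence)
        assert np.sum(scores > cut) <= prevalence * n

    @given(n=st.integers(1, 200), prevalence=st.floats(0.0, 1.0))
    def test_tie_free_exceed_count_is_floor(self, n, prevalence):
        scores = np.arange(n, dtype=float)
        cut = cc.calibrate_high_cutoff(scores, prevalence)
        assert int(np.sum(scores > cut)) == math.floor(n * prevalence)

    def test_empty_scores_rejected(self):
        with pytest.raises(cc.ValidationError):
            cc.calibrate_high_cutoff([], 0.1)


class TestCalibrateLowCutoff:
    def test_worked_example(self):
        cut = cc.calibrate_low_cutoff([1, 2, 3, 4], [0, 0, 1, 1])
        assert cut == 2.0  # NPV = 1 with the largest low-risk group

    def test_all_negative_tie_breaks_to_max_cutoff(self):
        # NPV = 1 at every cut-off; the largest low-risk group wins
        assert cc.calibrate_low_cutoff([0.1, 0.4, 0.7], [0, 0, 0]) == 0.7

    def test_npv_one_everywhere_returns_max_candidate(self):
        # one positive with the top score: every cut-off below it has NPV 1;
        # tie-break returns the largest low-risk group
        scores = [0.1, 0.2, 0.3, 0.9]
        cut = cc.calibrate_low_cutoff(scores, [0, 0, 0, 1])
        assert cut == 0.3

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(60):
            n = rng.integers(4, 201)
            scores = rng.choice(np.round(np.linspace(0, 1, 25), 3), size=n)
            outcomes = rng.integers(0, 2, n)
            if outcomes.min() == outcomes.max():
                continue
            cut = cc.calibrate_low_cutoff(scores, outcomes)
            oracle_cut, oracle_npv = brute_force_low_cutoff(scores, outcomes)
            assert cut == oracle_cut
            mask = scores <= cut
            assert np.mean(outcomes[mask] == 0) == pytest.approx(oracle_npv)


class TestStrata:
    def test_boundary_conventions(self):
        strata = cc.RiskStrata(low_cutoff=0.2, high_cutoff=0.6)
        assert cc.stratify(0.2, strata) is cc.RiskLevel.Low
        assert cc.stratify(0.6, strata) is cc.RiskLevel.Medium
        assert cc.stratify(0.61, strata) is cc.RiskLevel.High
        assert cc.stratify(0.19, strata) is cc.RiskLevel.Low

    def test_degenerate_strata_empty_medium(self):
        strata = cc.RiskStrata(low_cutoff=0.5, high_cutoff=0.5)
        assert cc.stratify(0.5, strata) is cc.RiskLevel.Low
        assert cc.stratify(0.50001, strata) is cc.RiskLevel.High

    def test_inverted_cutoffs_rejected(self):
        with pytest.raises(cc.ValidationError):
            cc.RiskStrata(low_cutoff=0.7, high_cutoff=0.6)

    def test_calibrate_strata_clamps_inverted_pair(self, caplog):
        # every score below the high cut-off is outcome-free, so the
        # NPV-optimal low cut-off lands above the high cut-off
        scores = np.array([0.1, 0.2, 0.3, 0.4, 0.9, 0.95])
        outcomes = np.array([0, 0, 0, 0, 1, 1])
        strata = cc.calibrate_strata(scores, outcomes, prevalence=0.5)
        assert strata.low_cutoff <= strata.high_cutoff


class TestPerformanceReport:
    def _fixture(self):
        # TP=5 FP=5 FN=5 TN=85 under the high-vs-outcome convention
        scores = np.array([0.9] * 10 + [0.1] * 90)
        outcomes = np.array([1] * 5 + [0] * 5 + [1] * 5 + [0] * 85)
        strata = cc.RiskStrata(low_cutoff=0.3, high_cutoff=0.5)
        return scores, outcomes, strata

    def test_counts_and_metrics(self):
        scores, outcomes, strata = self._fixture()
        rep = cc.performance_report(scores, outcomes, strata)
        assert rep.counts == {"tp": 5, "fp": 5, "fn": 5, "tn": 85}
        assert rep.sensitivity == pytest.approx(0.5)
        assert rep.specificity == pytest.approx(85 / 90)
        assert rep.ppv == pytest.approx(0.5)
        assert rep.npv == pytest.approx(85 / 90)
        total = sum(rep.counts.values())
        assert total == len(scores)

    def test_perfect_separation_all_metrics_one(self):
        scores = np.array([0.9, 0.95, 0.05, 0.1])
        outcomes = np.array([1, 1, 0, 0])
        strata = cc.RiskStrata(low_cutoff=0.5, high_cutoff=0.5)
        rep = cc.performance_report(scores, outcomes, strata)
        assert (rep.sensitivity, rep.specificity, rep.ppv, rep.npv, rep.auc) == (
            1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_convention_swap_is_bookkeeping_only(self):
        scores, outcomes, strata = self._fixture()
        high = cc.performance_report(scores, outcomes, strata, "high-vs-outcome")
        low = cc.performance_report(scores, outcomes, strata, "low-vs-no-outcome")
        assert sum(high.counts.values()) == sum(low.counts.values())
        assert high.auc == low.auc
        # under low-vs-no-outcome the condition is outcome absence
        assert low.counts["tp"] + low.counts["fn"] == int(np.sum(outcomes == 0))

    def test_zero_denominator_reported_as_undefined(self):
        scores = np.array([0.1, 0.2, 0.3, 0.9])
        outcomes = np.array([0, 0, 1, 1])
        strata = cc.RiskStrata(low_cutoff=0.95, high_cutoff=0.99)  # nobody High
        rep = cc.performance_report(scores, outcomes, strata)
        assert rep.ppv is None
        assert rep.sensitivity == 0.0


class TestStepwise:
    def test_no_candidates_returns_intercept_only(self, small_cohort):
        result = cc.stepwise_auc_select(small_cohort, "ebd_outcome", [])
        assert result.model.coefficients == {}
        assert result.trace == []

    def test_single_true_effect_recovered_without_noise_covariates(self):
        frame = cc.generate_cohort_frame(
            cc.CohortConfig(
                n=2000,
                seed=21,
                n_null_covariates=2,
                ebd_effects={"bullied": 1.0},
                ebd_prevalence=0.2,
            )
        )
        result = cc.stepwise_auc_select(
            frame, "ebd_outcome", ["bullied", "noise_1", "noise_2"]
        )
        assert set(result.model.coefficients) == {"bullied"}

    def test_trace_auc_strictly_increasing_and_above_half(self, small_cohort):
        result = cc.stepwise_auc_select(
            small_cohort, "ebd_outcome", ["bullied", "victimised", "sedentary_hours"]
        )
        aucs = [s.auc for s in result.trace]
        assert all(a > b for a, b in zip(aucs[1:], aucs[:-1]))
        assert all(a > 0.5 for a in aucs)
        final_auc = cc.auc(
            result.model.predict_frame(small_cohort), small_cohort["ebd_outcome"]
        )
        assert final_auc >= 0.5

    def test_separating_candidate_skipped_not_fatal(self):
        rng = np.random.default_rng(3)
        n = 400
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(x)).astype(int)
        frame = pd.DataFrame({"x": x, "y": y, "sep": y.astype(float)})
        result = cc.stepwise_auc_select(frame, "y", ["sep", "x"])
        assert "sep" not in result.model.coefficients
        assert "x" in result.model.coefficients


class TestSerialisation:
    def test_round_trips_exactly(self, tmp_path):
        model = cc.RiskModel(
            "cardio_outcome",
            intercept=-3.3219280948873623,
            coefficients={"adjusted_bmi_z": 0.9955988714090251},
            p_values={"adjusted_bmi_z": 1.51e-12},
        )
        strata = cc.RiskStrata(low_cutoff=0.046425146482841254, high_cutoff=0.17670674875897202)
        path = tmp_path / "model.json"
        cc.save_risk_document(path, model, strata, metadata={"seed": 11, "n": 1500})
        model2, strata2, meta = cc.load_risk_document(path)
        assert model2 == model
        assert strata2 == strata
        assert meta == {"seed": 11, "n": 1500}
        # floats survive the JSON text exactly
        doc = json.loads(path.read_text())
        assert doc["model"]["intercept"] == model.intercept
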
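"""ROC/DeLong, calibration, decision curves, Shapley, subgroups, sample size."""

import numpy as np
import pandas as pd
import pytest

from habitatmsi.evaluation import (
    SampleSizeSpec,
    calibration_brier,
    cohort_summary,
    decision_curve,
    delong_test,
    evaluate_model,
    required_sample_size,
    roc_auc,
    shapley_attribution,
    subgroup_eval,
    youden_threshold,
)


def brute_force_auc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    c = 0.0
    for p in pos:
        for q in neg:
            c += 1.0 if p > q else 0.5 if p == q else 0.0
    return c / (len(pos) * len(neg))


class TestRocAuc:
    def test_worked_example(self):
        auc, _ = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert auc == 0.75

    def test_perfect_and_all_ties(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])[0] == 1.0
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1])[0] == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_equals_brute_force_concordance(self, rng):
        for n in (10, 50, 200):
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            auc, _ = roc_auc(scores, labels)
            assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_ci_brackets_point(self, rng):
        scores = rng.random(80)
        labels = rng.integers(0, 2, 80)
        labels[:5], labels[-5:] = 1, 0
        auc, (lo, hi) = roc_auc(scores, labels)
        assert lo <= auc <= hi


class TestDelong:
    def test_identical_models(self, rng):
        s = rng.random(30)
        y = rng.integers(0, 2, 30)
        y[0], y[1] = 0, 1
        z, p = delong_test(s, s, y)
        assert z == 0.0 and p == 1.0

    def test_antisymmetry(self, rng):
        a, b = rng.random(40), rng.random(40)
        y = np.array([0, 1] * 20)
        z1, p1 = delong_test(a, b, y)
        z2, p2 = delong_test(b, a, y)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_agrees_with_bootstrap_oracle(self):
        rng = np.random.default_rng(7)
        n = 20
        y = np.array([1] * 8 + [0] * 12)
        a = y + rng.normal(scale=1.0, size=n)
        b = y + rng.normal(scale=1.6, size=n)
        _, p = delong_test(a, b, y)
        pos, neg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
        diffs = np.empty(10_000)
        for i in range(10_000):
            idx = np.concatenate(
                [rng.choice(pos, len(pos)), rng.choice(neg, len(neg))]
            )
            diffs[i] = roc_auc(a[idx], y[idx])[0] - roc_auc(b[idx], y[idx])[0]
        frac = (diffs < 0).mean() + 0.5 * (diffs == 0).mean()
        p_boot = 2 * min(frac, 1 - frac)
        assert abs(p - p_boot) < 0.05


class TestCalibrationBrier:
    def test_oracle_probabilities(self):
        _, brier = calibration_brier([0.0, 1.0, 1.0, 0.0], [0, 1, 1, 0])
        assert brier == 0.0

    def test_constant_half(self, rng):
        y = rng.integers(0, 2, 100)
        _, brier = calibration_brier(np.full(100, 0.5), y)
        assert brier == 0.25

    def test_calibrated_simulation_bins(self):
        rng = np.random.default_rng(3)
        probs = rng.random(2000)
        labels = rng.random(2000) < probs
        table, _ = calibration_brier(probs, labels.astype(int), n_bins=10)
        assert np.all(
            np.abs(table["observed_rate"] - table["mean_predicted"]) < 0.1
        )


class TestDecisionCurve:
    def test_treat_none_is_zero(self, rng):
        probs = rng.random(50)
        y = rng.integers(0, 2, 50)
        dca = decision_curve(probs, y, [0.1, 0.3, 0.5])
        assert (dca["treat_none"] == 0).all()

    def test_treat_all_formula(self):
        y = np.array([1] * 20 + [0] * 80)  # prevalence 0.2
        dca = decision_curve(np.full(100, 0.9), y, [0.5])
        assert dca["treat_all"].item() == pytest.approx(-0.6)

    def test_perfect_classifier_net_benefit_equals_prevalence(self):
        y = np.array([1] * 30 + [0] * 70)
        dca = decision_curve(y.astype(float), y, [0.1, 0.5, 0.9])
        assert np.allclose(dca["net_benefit"], 0.3)


class TestShapley:
    def test_additive_model_closed_form(self, rng):
        w = np.array([1.5, -2.0, 0.7])
        predict = lambda X: X @ w
        bg = rng.normal(size=(50, 3))
        x = np.array([1.0, 2.0, 3.0])
        phi, base = shapley_attribution(predict, x, bg)
        assert np.allclose(phi, w * (x - bg.mean(axis=0)), atol=1e-10)
        assert base == pytest.approx(predict(bg).mean())

    def test_dummy_feature_zero_attribution(self, rng):
        predict = lambda X: X[:, 0] ** 2
        bg = rng.normal(size=(30, 3))
        phi, _ = shapley_attribution(predict, [2.0, 5.0, -1.0], bg)
        assert phi[1] == 0.0 and phi[2] == 0.0

    def test_efficiency_identity_nonlinear(self, rng):
        predict = lambda X: np.tanh(X[:, 0] * X[:, 1]) + X[:, 2] ** 2
        bg = rng.normal(size=(40, 4))
        x = rng.normal(size=4)
        phi, base = shapley_attribution(predict, x, bg)
        f_case = predict(x.reshape(1, -1))[0]
        assert abs(phi.sum() - (f_case - base)) < 1e-6

    def test_dimension_limit(self, rng):
        with pytest.raises(ValueError):
            shapley_attribution(lambda X: X.sum(1), np.zeros(16), rng.normal(size=(5, 16)))


class TestSubgroups:
    def test_boundary_arithmetic(self):
        d = np.array([15.0, 20.0, 25.0, 30.0, 35.0])
        probs = np.array([0.1, 0.9, 0.2, 0.8, 0.6])
        labels = np.array([0, 1, 0, 1, 1])
        out = subgroup_eval(probs, labels, d)
        assert out["<=20mm"].n == 2
        assert out[">20-30mm"].n == 2
        assert out[">30mm"].n == 1

    def test_partition_no_loss_no_overlap(self, rng):
        d = rng.uniform(5, 50, 100)
        probs = rng.random(100)
        labels = rng.integers(0, 2, 100)
        out = subgroup_eval(probs, labels, d)
        assert sum(r.n for r in out.values()) == 100

    def test_single_class_stratum_flagged_not_raised(self):
        out = subgroup_eval([0.2, 0.4], [0, 0], [10.0, 12.0])
        assert out["<=20mm"].single_class
        assert np.isnan(out["<=20mm"].auc)


class TestSampleSize:
    def test_worked_example_p80(self):
        ns, _ = required_sample_size([0.80])
        assert ns == [97]  # ceil(1.96^2 * 0.16 / 0.0064)

    def test_sens_spec_pair_total(self):
        _, total = required_sample_size([0.80, 0.70])
        assert total == 224

    def test_maximized_at_half(self):
        sizes = [required_sample_size([p])[1] for p in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert max(sizes) == required_sample_size([0.5])[1]

    def test_degenerate_proportion(self):
        ns, total = required_sample_size([0.0, 1.0])
        assert ns == [0, 0] and total == 0


class TestCohortSummary:
    def test_identical_groups_t_test_p_one(self, rng):
        vals = rng.normal(50, 5, 60)
        df = pd.DataFrame(
            {"v": np.concatenate([vals, vals]), "g": ["a"] * 60 + ["b"] * 60}
        )
        out = cohort_summary(df, "g", ["v"])
        assert out["test"].item() == "t-test"
        assert out["p_value"].item() == pytest.approx(1.0, abs=1e-9)

    def test_chi_square_hand_computed(self):
        df = pd.DataFrame(
            {
                "x": ["yes"] * 30 + ["no"] * 10 + ["yes"] * 10 + ["no"] * 30,
                "g": ["a"] * 40 + ["b"] * 40,
            }
        )
        out = cohort_summary(df, "g", ["x"])
        assert out["statistic"].item() == pytest.approx(20.0)
        assert not np.isnan(out["p_value_corrected"].item())

    def test_skewed_variable_routed_to_rank_test(self, rng):
        v = np.exp(rng.normal(0, 1.2, 200))  # log-normal
        df = pd.DataFrame({"v": v, "g": ["a", "b"] * 100})
        out = cohort_summary(df, "g", ["v"])
        assert out["test"].item() == "mann-whitney"


class TestEvaluateModel:
    def test_metric_panel_consistency(self, rng):
        y = np.array([1] * 20 + [0] * 60)
        probs = np.clip(0.6 * y + rng.normal(scale=0.25, size=80), 0, 1)
        t = youden_threshold(probs, y)
        rep = evaluate_model(probs, y, t)
        for val, (lo, hi) in [
            (rep.accuracy, rep.accuracy_ci),
            (rep.sensitivity, rep.sensitivity_ci),
            (rep.specificity, rep.specificity_ci),
        ]:
            assert lo <= val <= hi
        assert 0 <= rep.brier <= 1
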
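"""Rebalancing, standardization, selection, association and the model grid."""

import numpy as np
import pandas as pd
import pytest

from habitatmsi.modeling import (
    CohortTagError,
    FeatureSelectionSpec,
    ModelGridSpec,
    ResampleSpec,
    grid_train,
    logistic_assoc,
    select_features,
    smote_resample,
    zscore_fit_apply,
)


class TestSmote:
    def _data(self, n_min=32, n_maj=120, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(1, 1, (n_min, 3)), rng.normal(-1, 1, (n_maj, 3))])
        y = np.array([1] * n_min + [0] * n_maj)
        return X, y

    def test_count_arithmetic_default_parameters(self):
        # minority 32, perc_over 200 -> 64 synthetic, minority total 96;
        # perc_under 155 -> majority kept = round(1.55 * 64) = 99
        X, y = self._data()
        Xr, yr = smote_resample(X, y, ResampleSpec(seed=1))
        assert int((yr == 1).sum()) == 96
        assert int((yr == 0).sum()) == 99

    def test_interpolation_geometry_two_points(self):
        X = np.array([[0.0, 0.0], [1.0, 2.0], [10.0, 10.0], [11.0, 10.0],
                      [12.0, 10.0], [13.0, 10.0]])
        y = np.array([1, 1, 0, 0, 0, 0])
        Xr, yr = smote_resample(X, y, ResampleSpec(perc_over=100, k_neighbors=1, seed=0))
        synth = Xr[2 : int((yr == 1).sum())]
        for s in synth:
            # lies on the segment between the two minority points
            lam = s[1] / 2.0
            assert 0 <= lam <= 1
            assert s[0] == pytest.approx(lam * 1.0)

    def test_seed_determinism(self):
        X, y = self._data()
        a = smote_resample(X, y, ResampleSpec(seed=9))
        b = smote_resample(X, y, ResampleSpec(seed=9))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_non_training_cohort_refused(self):
        X, y = self._data()
        with pytest.raises(CohortTagError):
            smote_resample(X, y, cohort_tag="val")

    def test_tiny_minority_rejected(self):
        X, y = self._data(n_min=3)
        with pytest.raises(ValueError):
            smote_resample(X, y, ResampleSpec(k_neighbors=5))


class TestZScore:
    def test_train_standardized_others_use_train_params(self, rng):
        Xt = rng.normal(5, 2, (100, 4))
        Xv = rng.normal(9, 2, (40, 4))  # different mean: must NOT center to 0
        (Zt, Zv), params = zscore_fit_apply(Xt, Xv)
        assert np.allclose(Zt.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(Zt.std(axis=0), 1, atol=1e-9)
        assert np.all(np.abs(Zv.mean(axis=0)) > 0.5)

    def test_constant_column_flagged_and_centered(self, rng):
        Xt = np.column_stack([np.full(50, 3.0), rng.normal(size=50)])
        (Zt,), params = zscore_fit_apply(Xt)
        assert params.constant_columns[0] and not params.constant_columns[1]
        assert np.allclose(Zt[:, 0], 0.0)

    def test_cohort_tag_guard(self, rng):
        with pytest.raises(CohortTagError):
            zscore_fit_apply(rng.normal(size=(10, 2)), cohort_tag="test")


class TestSelectFeatures:
    def test_informative_feature_recovered(self, rng):
        hits = 0
        for rep in range(20):
            n = 200
            y = rng.integers(0, 2, n)
            X = rng.normal(size=(n, 20))
            X[:, 0] += 2.0 * y  # effect size 2 sd
            df = pd.DataFrame(X, columns=[f"f{i}" for i in range(20)])
            res = select_features(df, y, FeatureSelectionSpec(rfe_keep=10, seed=rep))
            hits += "f0" in res.selected
        assert hits >= 19  # >= 95% recovery

    def test_huge_alpha_triggers_fallback(self, rng):
        n = 80
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 5))
        X[:, 0] += 1.5 * y
        df = pd.DataFrame(X, columns=[f"f{i}" for i in range(5)])
        spec = FeatureSelectionSpec(
            rfe_keep=5, lasso_alpha_grid=(1e6, 1e7, 1e8), cv_folds=3, seed=0
        )
        res = select_features(df, y, spec)
        assert res.empty_fallback
        assert len(res.selected) >= 1

    def test_duplicated_column_not_both_kept(self, rng):
        n = 150
        y = rng.integers(0, 2, n)
        base = rng.normal(size=(n, 6))
        base[:, 0] += 1.5 * y
        X = np.column_stack([base, base[:, 0]])  # f6 duplicates f0
        df = pd.DataFrame(X, columns=[f"f{i}" for i in range(7)])
        res = select_features(df, y, FeatureSelectionSpec(rfe_keep=3, seed=0))
        assert not ({"f0", "f6"} <= set(res.selected))

    def test_cohort_tag_guard(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        with pytest.raises(CohortTagError):
            select_features(df, rng.integers(0, 2, 30), cohort_tag="val")


class TestLogisticAssoc:
    def test_closed_form_or_2x2(self):
        # exposure/outcome table: a=30 b=10 / c=10 d=30 -> OR = 30*30/(10*10) = 9
        x = np.array([1] * 40 + [0] * 40)
        y = np.array([1] * 30 + [0] * 10 + [1] * 10 + [0] * 30)
        df = pd.DataFrame({"x": x, "y": y})
        res = logistic_assoc(df, "y", ["x"])
        assert res["or"].item() == pytest.approx(9.0, rel=1e-4)

    def test_null_or_near_one(self, rng):
        x = rng.integers(0, 2, 400)
        y = rng.integers(0, 2, 400)
        df = pd.DataFrame({"x": x, "y": y})
        res = logistic_assoc(df, "y", ["x"])
        assert 0.8 <= res["or"].item() <= 1.25

    def test_independent_variable_small_coefficient(self, rng):
        ok = 0
        for rep in range(20):
            r = np.random.default_rng(rep)
            x = r.normal(size=300)
            y = r.integers(0, 2, 300)
            df = pd.DataFrame({"x": x, "y": y})
            res = logistic_assoc(df, "y", ["x"])
            se = (np.log(res["ci_high"].item()) - np.log(res["or"].item())) / 1.96
            ok += abs(res["coefficient"].item()) < 3 * se
        assert ok >= 18  # >= 90%

    def test_multivariate_takes_univariate_significant(self, rng):
        n = 300
        x1 = rng.normal(size=n)
        y = (x1 + rng.normal(scale=0.8, size=n) > 0).astype(int)
        x2 = rng.normal(size=n)  # noise
        df = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
        uni = logistic_assoc(df, "y", ["x1", "x2"], mode="univariate")
        multi = logistic_assoc(df, "y", ["x1", "x2"], mode="multivariate")
        sig = set(uni.loc[uni["p_value"] < 0.05, "variable"])
        assert "x1" in set(multi["variable"])
        assert set(multi["variable"]) == sig

    def test_perfect_separation_flagged(self):
        x = np.array([0.0] * 20 + [1.0] * 20)
        y = np.array([0] * 20 + [1] * 20)
        df = pd.DataFrame({"x": x, "y": y})
        res = logistic_assoc(df, "y", ["x"])
        assert bool(res["separation_flag"].item())


class TestGridTrain:
    def _separable(self, rng, n=60):
        y = np.array([0, 1] * (n // 2))
        X = rng.normal(size=(n, 3))
        X[:, 0] += 6.0 * y
        return X, y

    def test_full_default_grid_has_20_candidates(self, rng):
        X, y = self._separable(rng)
        res = grid_train((X[:40], y[:40]), (X[40:], y[40:]))
        assert len(res.candidates) == 20
        assert len(res.ranking) == 20

    def test_restricted_grid_returns_that_pair(self, rng):
        X, y = self._separable(rng)
        grid = ModelGridSpec(preprocessors=("maxabs",), classifiers=("logistic",))
        res = grid_train((X[:40], y[:40]), (X[40:], y[40:]), grid)
        assert res.best.preprocessor_name == "maxabs"
        assert res.best.classifier_name == "logistic"

    def test_separable_data_perfect_validation_auc(self, rng):
        X, y = self._separable(rng, n=80)
        res = grid_train((X[:50], y[:50]), (X[50:], y[50:]))
        assert res.ranking["val_auc"].max() == 1.0

    def test_single_class_validation_rejected(self, rng):
        X, y = self._separable(rng)
        with pytest.raises(ValueError):
            grid_train((X, y), (X[:5], np.zeros(5, dtype=int)))

    def test_unknown_grid_entry_rejected(self):
        with pytest.raises(ValueError):
            ModelGridSpec(preprocessors=("pca",))
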
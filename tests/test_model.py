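"""Published equation, PLS fitting, validation statistics and binning."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from benzoqsar import (ActivityBin, PLSActivityModel, PublishedActivityModel,
                       bin_activity, fit_pls, flag_outliers, loo_xr2,
                       predict_published, rmse, validate)
from benzoqsar.descriptors import DESCRIPTOR_NAMES
from benzoqsar.model import PUBLISHED_COEFFICIENTS, PUBLISHED_INTERCEPT


class TestPublishedModel:
    def test_zero_vector_returns_intercept(self):
        assert predict_published(np.zeros(5)) == 9.45416

    def test_unit_h_log_pbo(self):
        assert predict_published(np.array([1.0, 0, 0, 0, 0])) == \
            pytest.approx(9.45416 + 0.77505, abs=1e-12)

    def test_finite_difference_recovers_printed_coefficients(self):
        for k, name in enumerate(DESCRIPTOR_NAMES):
            e = np.zeros(5)
            e[k] = 1.0
            slope = predict_published(e) - predict_published(np.zeros(5))
            assert slope == pytest.approx(PUBLISHED_COEFFICIENTS[name],
                                          abs=1e-12)

    def test_exactly_affine(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=5)
        # doubling one descriptor moves the prediction by coef × increment
        for k in range(5):
            bumped = x.copy()
            bumped[k] *= 2
            delta = predict_published(bumped) - predict_published(x)
            coef = PUBLISHED_COEFFICIENTS[DESCRIPTOR_NAMES[k]]
            assert delta == pytest.approx(coef * x[k], abs=1e-10)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="finite"):
            PublishedActivityModel().predict(
                np.array([[np.nan, 0, 0, 0, 0]]))


class TestPLSFit:
    def test_noiseless_recovery_at_full_rank(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 5))
        beta = np.array([1.5, -2.0, 0.3, 0.0, 4.0])
        y = 2.0 + X @ beta
        model = PLSActivityModel(n_components=5).fit(X, y)
        np.testing.assert_allclose(model.coef_, beta, atol=1e-8)
        assert model.intercept_ == pytest.approx(2.0, abs=1e-8)
        assert model.r2_train_ == pytest.approx(1.0, abs=1e-10)

    def test_single_descriptor_equals_ols(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = 1.0 + 3.0 * x + 0.1 * rng.normal(size=30)
        model = PLSActivityModel(n_components=1).fit(x.reshape(-1, 1), y)
        slope = np.cov(x, y, bias=True)[0, 1] / np.var(x)
        intercept = y.mean() - slope * x.mean()
        assert model.coef_[0] == pytest.approx(slope, abs=1e-10)
        assert model.intercept_ == pytest.approx(intercept, abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_coefficients_recovered_under_noise(self, seed):
        # well-conditioned descriptors at realistic scales, σ = 0.3
        rng = np.random.default_rng(seed)
        scales = np.array([0.5, 0.45, 30.0, 25.0, 14.0])
        X = rng.normal(size=(67, 5)) * scales
        beta = np.array([PUBLISHED_COEFFICIENTS[n] for n in DESCRIPTOR_NAMES])
        y = PUBLISHED_INTERCEPT + X @ beta + rng.normal(0, 0.3, size=67)
        model = PLSActivityModel(n_components=5).fit(
            pd.DataFrame(X, columns=DESCRIPTOR_NAMES), y)
        assert np.all(np.sign(model.coef_) == np.sign(beta))
        rel_err = np.abs((model.coef_ - beta) / beta)
        assert np.all(rel_err <= 0.20)

    def test_auto_latent_count_reported(self, library_dataset,
                                        library_activities):
        model = fit_pls(library_dataset.descriptors, library_activities)
        assert 1 <= model.n_components_ <= 5
        assert model.xr2_ <= 1.0 and model.r2_train_ <= 1.0

    def test_constant_activity_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            PLSActivityModel().fit(np.eye(5), np.ones(5))

    def test_zero_variance_column_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"live": rng.normal(size=30),
                          "dead": np.full(30, 7.0)})
        y = X["live"].to_numpy() * 2 + 1
        with pytest.warns(UserWarning, match="zero-variance"):
            model = PLSActivityModel(n_components=1).fit(X, y)
        assert model.coef_[1] == 0.0
        assert model.predict(X) == pytest.approx(y, abs=1e-8)


class TestLooXr2:
    @staticmethod
    def oracle(X, y, k):
        """Independent leave-one-out loop via np.delete."""
        press = 0.0
        for i in range(len(y)):
            pls = PLSRegression(n_components=k).fit(
                np.delete(X, i, axis=0), np.delete(y, i))
            press += (y[i] - pls.predict(X[i:i + 1]).ravel()[0]) ** 2
        return 1 - press / np.sum((y - y.mean()) ** 2)

    def test_perfect_linear_data_gives_one(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 2))
        y = X @ np.array([1.0, -1.0]) + 5
        assert loo_xr2(X, y, 2) == pytest.approx(1.0, abs=1e-8)

    def test_matches_explicit_loop_oracle(self, library_dataset,
                                          library_activities):
        X = library_dataset.descriptors.to_numpy()[:25]
        y = library_activities[:25]
        for k in (1, 2, 3):
            assert loo_xr2(X, y, k) == pytest.approx(self.oracle(X, y, k),
                                                     abs=1e-10)

    def test_pure_noise_negative_in_expectation(self):
        values = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(20, 3))
            y = rng.normal(size=20)
            values.append(loo_xr2(X, y, 1))
        assert np.mean(values) < 0

    def test_never_exceeds_training_r2(self, library_dataset,
                                       library_activities):
        X, y = library_dataset.descriptors, library_activities
        for k in (1, 3, 5):
            model = PLSActivityModel(n_components=k).fit(X, y)
            assert model.xr2_ <= model.r2_train_ + 1e-10

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            loo_xr2(np.ones((2, 1)), np.array([1.0, 2.0]), 1)


class _FixedModel:
    def __init__(self, values):
        self._values = np.asarray(values, dtype=float)

    def predict(self, X):
        return self._values[:len(np.asarray(X))]


class TestValidate:
    def test_perfect_predictions(self):
        y = np.array([6.1, 7.2, 8.3, 6.6])
        report = validate(_FixedModel(y), np.zeros((4, 1)), y)
        assert report.r2_test == pytest.approx(1.0)
        assert report.rmse_test == pytest.approx(0.0)
        assert report.outliers == []

    def test_constant_offset_moves_rmse_not_r2(self):
        rng = np.random.default_rng(5)
        y = rng.normal(7, 0.5, size=12)
        base = validate(_FixedModel(y), np.zeros((12, 1)), y)
        shifted = validate(_FixedModel(y + 0.8), np.zeros((12, 1)), y)
        assert shifted.rmse_test == pytest.approx(0.8, abs=1e-12)
        assert shifted.r2_test == pytest.approx(base.r2_test, abs=1e-12)

    def test_removing_largest_residuals_lowers_rmse(self):
        y = np.array([7.0, 7.5, 8.0, 6.5, 7.2, 6.8, 7.7, 8.1, 7.4])
        pred = y + np.array([0.1, -0.1, 2.0, 0.2, -0.2, 0.1, -1.5, 0.0, 0.1])
        full = rmse(y, pred)
        worst = np.argsort(np.abs(pred - y))[-2:]
        keep = np.setdiff1d(np.arange(len(y)), worst)
        assert rmse(y[keep], pred[keep]) < full

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            validate(_FixedModel([]), np.zeros((0, 1)), [])


class TestFlagOutliers:
    def test_examples(self):
        exp = [7.0, 7.0, 7.0]
        ids = ["a", "b", "c"]
        assert flag_outliers(["x"], [7.0], [10.0]) == [("x", 3.0)]
        assert flag_outliers(["x"], [7.0], [9.5]) == []   # exactly 2.5
        flagged = flag_outliers(ids, exp, [7.1, 9.6, 8.0])
        assert [f[0] for f in flagged] == ["b"]

    def test_absolute_rule_catches_under_prediction(self):
        assert flag_outliers(["u"], [9.0], [6.0]) == [("u", 3.0)]
        assert flag_outliers(["u"], [9.0], [6.0], absolute=False) == []

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            flag_outliers(["a"], [np.nan], [7.0])


class TestBinActivity:
    @pytest.mark.parametrize("value, expected", [
        (8.61, ActivityBin.HIGH),       # phenazepam's predicted potency
        (7.50, ActivityBin.MEDIUM),     # diazepam's predicted potency
        (6.99, ActivityBin.LOW),
        (7.00, ActivityBin.MEDIUM),
        (7.99, ActivityBin.MEDIUM),
        (8.00, ActivityBin.HIGH),
        (5.80, ActivityBin.LOW),
        (12.0, ActivityBin.HIGH),
    ])
    def test_boundaries(self, value, expected):
        assert bin_activity(value) is expected

    def test_below_span_is_out_of_range_with_warning(self):
        with pytest.warns(UserWarning, match="below the modelled range"):
            assert bin_activity(5.79) is ActivityBin.OUT_OF_RANGE

    def test_partition_is_total_and_disjoint(self):
        for value in np.arange(5.80, 12.0, 0.01):
            assert bin_activity(round(value, 2)) in (
                ActivityBin.LOW, ActivityBin.MEDIUM, ActivityBin.HIGH)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            bin_activity(float("inf"))
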
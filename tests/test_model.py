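"""Screening models: design matrices, IRLS, LASSO path, CV, odds ratios."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from neckscreen import model as nsmodel
from neckscreen.model import (
    ModelSpec,
    SeparationError,
    StandardizationParams,
    build_design,
    cv_select_lambda,
    default_lambda_path,
    finalize_model,
    fit_lasso_path,
    fit_logistic_mle,
    lambda_max,
    lasso_kkt_violation,
    predict_prob,
    standard_specs,
    standardize,
)


def _records(n=200, seed=0, beta=(0.0, 1.0, -0.8), include_extras=True):
    """Synthetic record table with a known logistic law on standardised
    (median_pixel, iqr_pixel)."""
    rng = np.random.default_rng(seed)
    med = rng.normal(0.42, 0.1, n)
    iqr = rng.normal(0.1, 0.05, n)
    z_med = (med - med.mean()) / med.std(ddof=1)
    z_iqr = (iqr - iqr.mean()) / iqr.std(ddof=1)
    eta = beta[0] + beta[1] * z_med + beta[2] * z_iqr
    y = (rng.random(n) < expit(eta)).astype(int)
    data = {
        "subject_id": [f"s{i}" for i in range(n)],
        "outcome": y,
        "median_pixel": med,
        "iqr_pixel": iqr,
    }
    if include_extras:
        data["fast_density"] = rng.gamma(1.0, 0.7, n)
        data["age"] = rng.uniform(65, 100, n)
        data["sex"] = rng.choice(["female", "male"], n)
        data["bmi"] = rng.normal(20, 3, n)
    return pd.DataFrame(data)


class TestModelSpecs:
    def test_standard_specs_cover_the_six_variants(self):
        names = [s.name for s in standard_specs()]
        assert names == [
            "model1", "model1_no_image", "model2",
            "model2_no_image", "model3", "image_only",
        ]

    def test_model3_drops_median_pixel_only(self):
        m2 = set(ModelSpec.named("model2").covariates)
        m3 = set(ModelSpec.named("model3").covariates)
        assert m2 - m3 == {"median_pixel"}

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            ModelSpec.named("model9")


class TestBuildDesign:
    def test_image_only_column_order(self):
        X, y, cols = build_design(_records(30), ModelSpec.named("image_only"))
        assert cols == ["median_pixel", "iqr_pixel", "fast_density"]
        assert X.shape == (30, 3)

    @pytest.mark.parametrize("bmi,expected", [(18.5, 0.0), (18.49, 1.0), (25.0, 0.0)])
    def test_bmi_dichotomised_at_18_5(self, bmi, expected):
        records = _records(20)
        records["bmi"] = bmi
        X, _, cols = build_design(records, ModelSpec.named("model1"))
        assert X[0, cols.index("bmi_underweight")] == expected

    def test_sex_coded_female_one(self):
        records = _records(10)
        records["sex"] = ["female", "male"] * 5
        X, _, cols = build_design(records, ModelSpec.named("model1"))
        assert np.array_equal(X[:, cols.index("sex_female")], [1, 0] * 5)

    def test_missing_covariate_named_in_error(self):
        records = _records(10).drop(columns=["age"])
        with pytest.raises(KeyError, match="age"):
            build_design(records, ModelSpec.named("model2"))


class TestStandardize:
    def test_self_standardisation(self):
        rng = np.random.default_rng(1)
        X = rng.normal(10, 2, size=(50, 1))
        Xs, _ = standardize(X, ["age"])
        assert abs(Xs.mean()) < 1e-12
        assert abs(Xs.std(ddof=1) - 1) < 1e-12

    def test_binary_column_passes_through(self):
        X = np.column_stack([np.tile([0.0, 1.0], 10), np.arange(20.0)])
        Xs, _ = standardize(X, ["sex_female", "age"])
        assert np.array_equal(Xs[:, 0], X[:, 0])

    def test_train_params_applied_to_test(self):
        params = StandardizationParams(means={"age": 10.0}, sds={"age": 2.0})
        out = params.transform(np.array([[14.0]]), ["age"])
        assert out[0, 0] == 2.0

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            StandardizationParams.fit(np.ones((10, 1)), ["age"])


class TestLogisticMle:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(40), np.zeros(60)]
        beta, _ = fit_logistic_mle(np.empty((100, 0)), y)
        assert beta[0] == pytest.approx(np.log(0.4 / 0.6), abs=1e-8)

    def test_two_by_two_table_closed_form(self):
        # exposed: 10 cases / 20 controls; unexposed: 30 / 40
        x = np.r_[np.ones(30), np.zeros(70)][:, None]
        y = np.r_[np.ones(10), np.zeros(20), np.ones(30), np.zeros(40)]
        beta, _ = fit_logistic_mle(x, y)
        assert beta[1] == pytest.approx(np.log(2 / 3), abs=1e-8)

    def test_parameter_recovery_within_three_se(self):
        rng = np.random.default_rng(8)
        n = 2000
        X = rng.normal(size=(n, 2))
        truth = np.array([-0.5, 1.0, -0.8])
        y = (rng.random(n) < expit(truth[0] + X @ truth[1:])).astype(float)
        beta, cov = fit_logistic_mle(X, y)
        se = np.sqrt(np.diag(cov))
        assert (np.abs(beta - truth) <= 3 * se).all()

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        X = rng.normal(size=(300, 3))
        y = (rng.random(300) < expit(0.3 + X @ [0.5, -0.4, 0.0])).astype(float)
        beta, cov = fit_logistic_mle(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert np.allclose(beta, ref.params, atol=1e-6)
        assert np.allclose(np.sqrt(np.diag(cov)), ref.bse, atol=1e-6)

    def test_perfect_separation_flagged(self):
        x = np.r_[np.zeros(20), np.ones(20)][:, None]
        y = np.r_[np.zeros(20), np.ones(20)]
        with pytest.raises(SeparationError):
            fit_logistic_mle(x, y)


class TestLassoPath:
    @staticmethod
    def _xy(n=300, p=4, seed=5, beta=None):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        if beta is None:
            beta = np.r_[0.2, np.linspace(1, -1, p)]
        y = (rng.random(n) < expit(beta[0] + X @ beta[1:])).astype(float)
        return X, y

    def test_zero_penalty_matches_mle(self):
        X, y = self._xy()
        mle, _ = fit_logistic_mle(X, y)
        path = fit_lasso_path(X, y, np.append(default_lambda_path(X, y, 20), 0.0))
        assert np.abs(path[-1] - mle).max() < 1e-4

    def test_lambda_max_zeroes_all_slopes(self):
        X, y = self._xy()
        lmax = lambda_max(X, y)
        for lam in (lmax, 2 * lmax):
            coefs = fit_lasso_path(X, y, [lam])[0]
            assert np.array_equal(coefs[1:], np.zeros(X.shape[1]))

    def test_subgradient_conditions_along_path(self):
        X, y = self._xy()
        lambdas = default_lambda_path(X, y, 25)
        path = fit_lasso_path(X, y, lambdas)
        for lam, beta in zip(lambdas, path):
            assert lasso_kkt_violation(X, y, lam, beta) < 1e-6

    def test_single_covariate_shrinkage_monotone(self):
        X, y = self._xy(p=1, beta=np.array([0.0, 1.2]))
        lambdas = default_lambda_path(X, y, 30)
        path = fit_lasso_path(X, y, lambdas)
        slopes = np.abs(path[:, 1])
        assert (np.diff(slopes) >= -1e-9).all()  # |beta| grows as lambda falls

    def test_matches_sklearn_liblinear_family(self):
        # independent implementation cross-check at a few penalties
        sklearn_linear = pytest.importorskip("sklearn.linear_model")
        X, y = self._xy(n=400)
        n = len(y)
        for lam in (0.01, 0.05):
            ours = fit_lasso_path(X, y, [lambda_max(X, y), lam])[-1]
            ref = sklearn_linear.LogisticRegression(
                penalty="l1", C=1.0 / (n * lam), solver="saga",
                tol=1e-10, max_iter=50000,
            ).fit(X, y)
            assert np.abs(ours[1:] - ref.coef_.ravel()).max() < 1e-4
            assert abs(ours[0] - ref.intercept_[0]) < 1e-4

    def test_nondecreasing_lambdas_rejected(self):
        X, y = self._xy()
        with pytest.raises(ValueError, match="decreasing"):
            fit_lasso_path(X, y, [0.1, 0.1])


class TestCvSelectLambda:
    def test_deterministic_given_seed(self):
        X, y = TestLassoPath._xy()
        a = cv_select_lambda(X, y, seed=42)
        b = cv_select_lambda(X, y, seed=42)
        assert a == b

    def test_noise_covariates_prefer_sparse_fits(self):
        rng = np.random.default_rng(17)
        n = 500
        X = rng.normal(size=(n, 5))
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = (rng.random(n) < 0.4).astype(float)
        lam, lambdas, dev = cv_select_lambda(X, y, seed=1, return_details=True)
        coefs = fit_lasso_path(X, y, np.geomspace(lambda_max(X, y), lam, 20))[-1]
        assert (coefs[1:] != 0).sum() <= 2
        assert dev[np.argmin(np.abs(lambdas - lam))] <= dev[-1]

    def test_strong_signal_survives_selection(self):
        kept = 0
        reps = 30
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            n = 500
            X = rng.normal(size=(n, 3))
            X = (X - X.mean(0)) / X.std(0, ddof=1)
            y = (rng.random(n) < expit(2.0 * X[:, 0])).astype(float)
            lam = cv_select_lambda(X, y, seed=seed)
            coefs = fit_lasso_path(
                X, y, np.geomspace(lambda_max(X, y), lam, 15)
            )[-1]
            kept += coefs[1] != 0
        assert kept >= int(0.9 * reps)

    def test_single_class_folds_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        y = np.r_[np.ones(1), np.zeros(19)]  # one positive cannot fill 10 folds
        with pytest.raises(ValueError, match="fold"):
            cv_select_lambda(X, y, folds=10, seed=0)


class TestFinalizeAndPredict:
    def test_wald_interval_closed_form(self):
        # coef 0.5, SE 0.1 -> OR 1.6487, CI exp(0.5 -/+ 1.96 * 0.1)
        lo, hi = np.exp(0.5 - 1.96 * 0.1), np.exp(0.5 + 1.96 * 0.1)
        assert np.exp(0.5) == pytest.approx(1.6487, abs=1e-4)
        assert (lo, hi) == (pytest.approx(1.3553, abs=1e-4), pytest.approx(2.0057, abs=1e-4))

    def _fitted(self, records=None, spec=None, seed=0):
        records = _records(400, seed=2) if records is None else records
        spec = spec or ModelSpec.named("image_only")
        X, y, cols = build_design(records, spec)
        Xs, params = standardize(X, cols)
        lam = cv_select_lambda(Xs, y, seed=seed)
        return finalize_model(Xs, y, spec, lam, params, columns=cols), records

    def test_or_table_layout(self):
        fitted, _ = self._fitted()
        table = fitted.odds_ratios
        assert table["covariate"].iloc[0] == "intercept"
        assert set(table.columns) >= {"odds_ratio", "ci_low", "ci_high"}
        assert (table["ci_low"] <= table["odds_ratio"]).all()
        assert (table["odds_ratio"] <= table["ci_high"]).all()

    def test_refit_or_equals_exp_coefficient(self):
        fitted, _ = self._fitted()
        assert np.allclose(
            fitted.odds_ratios["odds_ratio"],
            np.exp(fitted.odds_ratios["coefficient"]),
        )

    def test_ci_coverage_in_simulation(self):
        # 200 replicates, n = 2000, true OR = 2 on one standardised covariate
        hits = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(30000 + seed)
            x = rng.normal(size=(2000, 1))
            y = (rng.random(2000) < expit(-0.3 + np.log(2.0) * x[:, 0])).astype(float)
            beta, cov = fit_logistic_mle(x, y)
            se = np.sqrt(cov[1, 1])
            lo, hi = np.exp(beta[1] - 1.96 * se), np.exp(beta[1] + 1.96 * se)
            hits += lo <= 2.0 <= hi
        assert 0.90 <= hits / reps <= 0.99

    def test_or_invariant_to_feature_scaling(self):
        records = _records(500, seed=6)
        fitted_a, _ = self._fitted(records=records)
        scaled = records.copy()
        scaled["fast_density"] *= 1000.0
        fitted_b, _ = self._fitted(records=scaled)
        a = fitted_a.odds_ratios.set_index("covariate")["odds_ratio"]
        b = fitted_b.odds_ratios.set_index("covariate")["odds_ratio"]
        assert np.allclose(a, b, rtol=1e-6)

    def test_predict_prob_intercept_only(self):
        records = _records(100, seed=4)
        spec = ModelSpec.named("image_only")
        X, y, cols = build_design(records, spec)
        Xs, params = standardize(X, cols)
        lmax = lambda_max(Xs, y)
        fitted = finalize_model(Xs, y, spec, 2 * lmax, params, columns=cols)
        assert fitted.selected_covariates == ()
        probs = predict_prob(fitted, records)
        assert np.allclose(probs, y.mean(), atol=1e-6)

    def test_predict_prob_monotone_in_positive_coefficient(self):
        fitted, records = self._fitted(records=_records(600, seed=9,
                                                        beta=(0.0, 1.5, -0.5)))
        coef = fitted.refit_coefficients.get("median_pixel", 0.0)
        assert coef > 0
        probe = records.head(1).copy()
        sweep = []
        for v in np.linspace(0.2, 0.7, 7):
            probe["median_pixel"] = v
            sweep.append(predict_prob(fitted, probe)[0])
        assert (np.diff(sweep) > 0).all()
        assert all(0 < p < 1 for p in sweep)
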
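"""Screening, penalized fitting, selection, validation and sensitivity ops."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from opmcg._solver import enet_logistic_path, fast_auc, standardize
from opmcg.exceptions import (
    InvalidArgumentError,
    NotTestableError,
    ScreeningEmptyError,
)
from opmcg.model import (
    AnginaLassoModel,
    SelectionResult,
    _fit_at_lambda,
    _stratified_resample,
    calibration_intercept_slope,
    decision_curve,
    delong_auc_variance,
    delong_ci,
    elastic_net_sensitivity,
    fit_final_model,
    permutation_importance,
    pool_group_summaries,
    predict_risk,
    screen_features,
    select_stable,
    spline_nonlinearity,
    stratified_bootstrap_lasso,
    validate_model,
)


def scipy_penalized_logistic(X, y, lam, alpha=1.0):
    """Independent convex-optimizer oracle for the elastic-net logistic fit."""
    n, p = X.shape

    def obj(params):
        b0, bp, bm = params[0], params[1:p + 1], params[p + 1:]
        b = bp - bm
        eta = b0 + X @ b
        nll = np.mean(np.logaddexp(0.0, eta) - y * eta)
        return nll + lam * (alpha * np.sum(bp + bm)
                            + (1 - alpha) / 2.0 * np.sum(b * b))

    res = minimize(obj, np.zeros(2 * p + 1), method="L-BFGS-B",
                   bounds=[(None, None)] + [(0, None)] * (2 * p),
                   options={"maxiter": 30000, "ftol": 1e-15, "gtol": 1e-12})
    return res.x[0], res.x[1:p + 1] - res.x[p + 1:]


def simple_table(n=200, p=6, beta=None, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = np.zeros(p) if beta is None else np.asarray(beta, float)
    y = (rng.random(n) < expit(X @ beta - 0.3)).astype(int)
    cols = [f"f{i}" for i in range(p)]
    df = pd.DataFrame(X, columns=cols)
    df["label"] = y
    return df, cols


class TestScreening:
    def test_constant_column_dropped(self):
        df, cols = simple_table(100)
        df["const"] = 1.0
        _, report = screen_features(df)
        assert "const" in report.variance_dropped

    def test_duplicate_column_resolved_once(self):
        df, cols = simple_table(100)
        df["dup"] = df["f0"]
        screened, report = screen_features(df)
        dropped = {d for d, _ in report.correlation_dropped}
        assert len(dropped & {"f0", "dup"}) == 1
        assert len(report.correlation_dropped) == 1

    def test_independent_columns_survive(self):
        df, cols = simple_table(1000, p=20, seed=5)
        screened, report = screen_features(df)
        assert report.surviving == tuple(cols)

    def test_idempotent(self):
        df, _ = simple_table(150, p=10, seed=2)
        df["dup"] = df["f1"] + 1e-6 * np.random.default_rng(0).standard_normal(150)
        once, r1 = screen_features(df)
        twice, r2 = screen_features(once)
        assert r2.dropped == ()
        pd.testing.assert_frame_equal(once, twice)

    def test_partition_into_dropped_and_surviving(self):
        df, cols = simple_table(100, p=8, seed=3)
        df["dup"] = df["f2"]
        df["const"] = 0.0
        _, report = screen_features(df)
        all_names = set(cols) | {"dup", "const"}
        assert set(report.dropped) | set(report.surviving) == all_names
        assert not set(report.dropped) & set(report.surviving)


class TestPenalizedSolver:
    def test_lasso_matches_convex_oracle_on_reference_instance(self):
        """5-feature, 40-subject instance: CD vs general-purpose optimizer."""
        rng = np.random.default_rng(7)
        X, _, _ = standardize(rng.standard_normal((40, 5)))
        y = (rng.random(40) < expit(X @ np.array([1.0, -0.5, 0.0, 0.3, 0.0]))
             ).astype(float)
        for lam in (0.005, 0.03, 0.1):
            b0, beta = _fit_at_lambda(X, y, lam, 1.0)
            b0_ref, beta_ref = scipy_penalized_logistic(X, y, lam, 1.0)
            assert np.abs(beta - beta_ref).max() < 1e-5
            assert abs(b0 - b0_ref) < 1e-5

    def test_elastic_net_matches_convex_oracle(self):
        rng = np.random.default_rng(8)
        X, _, _ = standardize(rng.standard_normal((60, 8)))
        y = (rng.random(60) < expit(X[:, 0] - 0.5 * X[:, 1])).astype(float)
        b0, beta = _fit_at_lambda(X, y, 0.05, 0.5)
        b0_ref, beta_ref = scipy_penalized_logistic(X, y, 0.05, 0.5)
        assert np.abs(beta - beta_ref).max() < 1e-5

    def test_ridge_keeps_every_coefficient(self):
        rng = np.random.default_rng(9)
        X, _, _ = standardize(rng.standard_normal((80, 6)))
        y = (rng.random(80) < expit(X[:, 0])).astype(float)
        _, beta = _fit_at_lambda(X, y, 0.05, 0.0)
        assert np.all(beta != 0.0)


class TestStabilitySelection:
    def test_resample_preserves_class_counts(self):
        rng = np.random.default_rng(0)
        idx_pos = np.arange(134)
        idx_neg = np.arange(134, 363)
        for _ in range(5):
            idx = _stratified_resample(rng, idx_pos, idx_neg)
            assert idx.size == 363
            assert np.sum(idx < 134) == 134
            assert np.sum(idx >= 134) == 229

    def test_strong_effect_always_selected_noise_rarely(self):
        df, cols = simple_table(240, p=8, beta=[1.2, 0, 0, 0, 0, 0, 0, 0],
                                seed=11)
        sr = stratified_bootstrap_lasso(df, n_boot=40, seed=11)
        frame = sr.summary_frame()
        assert frame.loc["f0", "frequency"] >= 0.9
        noise_freq = frame.drop("f0")["frequency"]
        assert (noise_freq < 0.7).mean() >= 0.75

    def test_selection_threshold_boundaries(self):
        sr = SelectionResult(feature_names=("a", "b", "c"),
                             counts=np.array([700.0, 699.0, 1000.0]),
                             coefs=np.zeros((1000, 3)), n_boot=1000)
        assert select_stable(sr) == ("a", "c")
        sr200 = SelectionResult(feature_names=("a", "b"),
                                counts=np.array([140.0, 139.0]),
                                coefs=np.zeros((200, 2)), n_boot=200)
        assert select_stable(sr200) == ("a",)

    def test_class_smaller_than_folds_rejected(self):
        df, _ = simple_table(30, seed=1)
        df["label"] = [1] * 5 + [0] * 25
        with pytest.raises(InvalidArgumentError):
            stratified_bootstrap_lasso(df, n_boot=2, n_folds=10, seed=0)


@pytest.fixture(scope="module")
def fitted():
    df, cols = simple_table(300, p=5, beta=[1.0, -0.8, 0.5, 0, 0], seed=21)
    fm = fit_final_model(df, cols, repeats=3, seed=21)
    return df, cols, fm


class TestFinalModel:
    def test_lambda_within_stated_range(self, fitted):
        _, _, fm = fitted
        assert 1e-4 <= fm.lam <= 10.0

    def test_standardization_stored_from_training_data(self, fitted):
        df, cols, fm = fitted
        X = df[cols].to_numpy()
        Z = (X - fm.means) / fm.sds
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(Z.std(axis=0), 1.0, atol=1e-12)

    def test_out_of_range_lambda_grid_rejected(self, fitted):
        df, cols, _ = fitted
        with pytest.raises(InvalidArgumentError):
            fit_final_model(df, cols, lambdas=np.array([50.0, 20.0]), seed=0)

    def test_empty_feature_list_rejected(self, fitted):
        df, _, _ = fitted
        with pytest.raises(InvalidArgumentError):
            fit_final_model(df, [], seed=0)

    def test_predictions_probabilistic_and_monotone(self, fitted):
        df, cols, fm = fitted
        p = predict_risk(fm, df)
        assert np.all((p > 0) & (p < 1))
        # at the training means the risk is expit(intercept)
        mid = predict_risk(fm, dict(zip(fm.features, fm.means)))
        assert mid[0] == pytest.approx(expit(fm.intercept))
        # monotone in a positive-coefficient feature
        k = int(np.argmax(fm.coef))
        row = dict(zip(fm.features, fm.means))
        lo = predict_risk(fm, row)[0]
        row[fm.features[k]] += fm.sds[k]
        hi = predict_risk(fm, row)[0]
        assert hi > lo

    def test_missing_feature_rejected(self, fitted):
        _, _, fm = fitted
        with pytest.raises(InvalidArgumentError):
            predict_risk(fm, {"nope": 1.0})


class TestDeLong:
    def test_perfect_separation(self):
        y = np.array([0] * 5 + [1] * 5)
        s = np.arange(10.0)
        auc, ci = delong_ci(y, s)
        assert auc == 1.0
        assert ci[1] == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 1000)
        s = rng.standard_normal(1000)
        auc, _ = delong_ci(y, s)
        assert auc == pytest.approx(0.5, abs=0.04)

    def test_variance_agrees_with_bootstrap(self):
        """DeLong variance vs 2,000-replicate bootstrap at n = 200."""
        rng = np.random.default_rng(5)
        y = np.array([1] * 80 + [0] * 120)
        s = np.where(y == 1, rng.normal(0.8, 1, 200), rng.normal(0, 1, 200))
        _, var = delong_auc_variance(y, s)
        boots = np.empty(2000)
        for b in range(2000):
            idx = rng.integers(0, 200, 200)
            while y[idx].min() == y[idx].max():
                idx = rng.integers(0, 200, 200)
            boots[b] = fast_auc(y[idx].astype(float), s[idx])
        assert var == pytest.approx(boots.var(ddof=1), rel=0.15)


class TestDecisionCurve:
    PROBS = np.array([0.9, 0.8, 0.7, 0.6, 0.55, 0.4, 0.3, 0.2, 0.15, 0.05])
    LABELS = np.array([1, 1, 1, 0, 1, 0, 0, 1, 0, 0])

    def test_hand_computed_fixture(self):
        dca = decision_curve(self.PROBS, self.LABELS,
                             thresholds=np.array([0.2, 0.5]))
        # pt=0.2: treat 8, TP=5, FP=3 -> 0.5 - 0.3*(0.2/0.8) = 0.425
        assert dca.loc[0, "net_benefit"] == pytest.approx(0.425)
        # pt=0.5: treat 5, TP=4, FP=1 -> 0.4 - 0.1*1 = 0.3
        assert dca.loc[1, "net_benefit"] == pytest.approx(0.3)

    def test_reference_curves(self):
        dca = decision_curve(self.PROBS, self.LABELS,
                             thresholds=np.array([0.2]))
        prev = self.LABELS.mean()
        assert dca.loc[0, "net_benefit_none"] == 0.0
        assert dca.loc[0, "net_benefit_all"] == pytest.approx(
            prev - (1 - prev) * 0.2 / 0.8)

    def test_perfect_classifier_attains_prevalence(self):
        probs = self.LABELS.astype(float) * 0.98 + 0.01
        dca = decision_curve(probs, self.LABELS,
                             thresholds=np.linspace(0.05, 0.95, 10))
        assert np.allclose(dca["net_benefit"], self.LABELS.mean())

    def test_net_benefit_never_exceeds_prevalence(self):
        rng = np.random.default_rng(2)
        probs = rng.random(300)
        labels = (rng.random(300) < probs).astype(int)
        dca = decision_curve(probs, labels)
        assert (dca["net_benefit"] <= labels.mean() + 1e-12).all()

    def test_threshold_one_excluded_invalid_rejected(self):
        dca = decision_curve(self.PROBS, self.LABELS,
                             thresholds=np.array([0.5, 1.0]))
        assert dca["threshold"].tolist() == [0.5]
        with pytest.raises(InvalidArgumentError):
            decision_curve(self.PROBS, self.LABELS, thresholds=np.array([0.0]))


class TestCalibration:
    def test_well_specified_simulation_recovers_identity(self):
        rng = np.random.default_rng(13)
        eta = rng.normal(-0.5, 1.2, 2000)
        p = expit(eta)
        y = (rng.random(2000) < p).astype(int)
        intercept, slope = calibration_intercept_slope(y, p)
        assert intercept == pytest.approx(0.0, abs=0.1)
        assert slope == pytest.approx(1.0, abs=0.1)


@pytest.fixture(scope="module")
def validated():
    df, cols = simple_table(300, p=5, beta=[1.0, -0.8, 0.5, 0, 0], seed=31)
    fm = fit_final_model(df, cols, repeats=2, seed=31)
    report = validate_model(fm, df, n_boot_roc=200, seed=31)
    return df, fm, report


class TestValidationReport:
    def test_auc_and_band_sane(self, validated):
        _, _, rep = validated
        assert 0.5 <= rep.auc_oriented <= 1.0
        assert rep.auc_ci[0] <= rep.auc <= rep.auc_ci[1]
        assert np.all(rep.roc_band_low <= rep.roc_band_high + 1e-12)

    def test_nomogram_points_affine_in_linear_predictor(self, validated):
        df, fm, rep = validated
        nomo = rep.nomogram
        X = df[list(fm.features)].to_numpy()
        Z = (X - fm.means) / fm.sds
        lp = fm.intercept + Z @ fm.coef
        total = np.zeros(len(df))
        for k, f in enumerate(fm.features):
            term = Z[:, k] * fm.coef[k]
            total += (term - nomo["terms"][f]["term_min"]) * nomo["scale"]
        # total points = scale * (lp - const): exactly affine
        corr = np.corrcoef(total, lp)[0, 1]
        assert corr == pytest.approx(1.0, abs=1e-12)
        widest = max(e["points_span"] for e in nomo["terms"].values())
        assert widest == pytest.approx(100.0)

    def test_stratum_calibration_skips_single_class(self, validated):
        df, fm, _ = validated
        df = df.copy()
        strat = np.where(np.arange(len(df)) < 20, "tiny", "rest")
        df.loc[df.index[:20], "label"] = 1  # single-class stratum
        df["grp"] = strat
        with pytest.warns(UserWarning):
            rep = validate_model(fm, df, strata=["grp"], n_boot_roc=20, seed=0)
        assert "grp=rest" in rep.stratum_calibration
        assert "grp=tiny" not in rep.stratum_calibration


class TestPermutationImportance:
    def test_zero_coefficient_feature_has_exactly_zero_drop(self):
        df, cols = simple_table(250, p=4, beta=[1.5, 0, 0, 0], seed=41)
        fm = fit_final_model(df, cols, repeats=2,
                             lambdas=np.logspace(-1, -2, 10), seed=41)
        assert np.any(fm.coef == 0.0)  # penalty zeroes the pure-noise columns
        drops = permutation_importance(fm, df, n_perm=10, seed=41)
        for k, f in enumerate(fm.features):
            if fm.coef[k] == 0.0:
                assert drops[f] == 0.0

    def test_dominant_feature_has_largest_drop_and_reproducible(self):
        df, cols = simple_table(250, p=4, beta=[1.5, 0.3, 0, 0], seed=42)
        fm = fit_final_model(df, cols, repeats=2, seed=42)
        d1 = permutation_importance(fm, df, n_perm=15, seed=7)
        d2 = permutation_importance(fm, df, n_perm=15, seed=7)
        assert d1.idxmax() == "f0"
        pd.testing.assert_series_equal(d1, d2)


class TestElasticNet:
    def test_alpha_one_reproduces_lasso(self):
        rng = np.random.default_rng(51)
        X, _, _ = standardize(rng.standard_normal((120, 6)))
        y = (rng.random(120) < expit(X[:, 0] - X[:, 1])).astype(float)
        lam = 0.02
        _, lasso = _fit_at_lambda(X, y, lam, 1.0)
        _, enet = _fit_at_lambda(X, y, lam, 1.0 + 0.0)
        assert np.abs(lasso - enet).max() < 1e-6
        # and against the independent oracle at alpha exactly 1
        _, ref = scipy_penalized_logistic(X, y, lam, 1.0)
        assert np.abs(lasso - ref).max() < 1e-5

    def test_sensitivity_close_to_lasso_model(self):
        df, cols = simple_table(200, p=6, beta=[1.0, -0.6, 0, 0, 0, 0], seed=52)
        lasso = fit_final_model(df, cols, repeats=1, seed=52)
        enet, report = elastic_net_sensitivity(
            df, alphas=(0.0, 0.5, 1.0), repeats=1,
            lambdas=np.logspace(1, -4, 20), seed=52)
        assert 0.0 <= enet.alpha <= 1.0
        assert abs(enet.cv_auc - lasso.cv_auc) < 0.05


class TestSplineNonlinearity:
    def test_p_value_in_unit_interval_and_linear_null_large(self):
        df, cols = simple_table(500, p=3, beta=[0.8, 0, 0], seed=61)
        p = spline_nonlinearity(df, "f0")
        assert 0.0 <= p <= 1.0

    def test_strong_quadratic_detected(self):
        rng = np.random.default_rng(62)
        x = rng.standard_normal(1000)
        y = (rng.random(1000) < expit(1.5 * x ** 2 - 1.0)).astype(int)
        df = pd.DataFrame({"x": x, "label": y})
        assert spline_nonlinearity(df, "x") < 1e-3

    def test_too_few_unique_values_not_testable(self):
        df = pd.DataFrame({"x": [0.0, 1.0] * 30,
                           "label": [0, 1, 1, 0] * 15})
        with pytest.raises(NotTestableError):
            spline_nonlinearity(df, "x")


class TestPooling:
    def test_size_weighted_mean_of_group_means(self):
        assert pool_group_summaries([21.45, 33.71], [134, 229],
                                    round_to=2) == 29.18

    def test_event_counts_to_percentage(self):
        assert pool_group_summaries([37], [363], kind="proportion",
                                    round_to=1) == 10.2

    def test_equal_group_means_pass_through(self):
        assert pool_group_summaries([5.0, 5.0], [10, 90]) == pytest.approx(5.0)

    def test_zero_size_rejected(self):
        with pytest.raises(InvalidArgumentError):
            pool_group_summaries([1.0], [0])


class TestModelResultsFrontDoor:
    def test_fit_summary_and_predict(self):
        df, cols = simple_table(220, p=6, beta=[1.3, -0.9, 0, 0, 0, 0], seed=71)
        res = AnginaLassoModel(df, screen=True).fit(n_boot=30, repeats=1, seed=71)
        assert "f0" in res.selected
        text = res.summary()
        assert "selection" in text.lower()
        p = res.predict(df)
        assert p.shape == (220,)
        rep = res.validate(n_boot_roc=50)
        assert rep.auc > 0.6

    def test_from_dataframe_renames_outcome(self):
        df, cols = simple_table(100, seed=72)
        df = df.rename(columns={"label": "angina"})
        model = AnginaLassoModel.from_dataframe(df, outcome="angina")
        assert "label" in model.table.columns
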
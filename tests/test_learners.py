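"""Bootstrap-shrunken logistic regression and tuned gradient-boosted trees."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit

import triagesim as ts
from triagesim import learners
from triagesim.exceptions import SchemaError, UnfittableError


@pytest.fixture(scope="module")
def design(balanced_design):
    return balanced_design


def tiny_dataset(seed=5, n=60):
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 2, size=(n, 3)).astype(float)
    logit = -0.5 + X @ np.array([0.8, -0.4, 1.2])
    y = (rng.random(n) < expit(logit)).astype(int)
    return X, y


class TestLogisticFit:
    def test_matches_unpenalized_mle_when_ridge_vanishes(self, design):
        """With a vanishing ridge the fit agrees with statsmodels ML to 1e-4."""
        X, y = design
        ours = learners.fit_logistic_irls(X, y, ridge=1e-10)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0, method="newton", tol=1e-12)
        assert np.allclose(ours, ref.params, atol=1e-4)

    def test_all_zero_column_gets_zero_coefficient(self):
        X, y = tiny_dataset()
        X = np.hstack([X, np.zeros((len(y), 1))])
        beta = learners.fit_logistic_irls(X, y)
        assert beta[-1] == pytest.approx(0.0, abs=1e-10)

    def test_separable_data_stays_finite_with_ridge(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array([0, 0, 1, 1])
        beta = learners.fit_logistic_irls(X, y, ridge=1e-4)
        assert np.all(np.isfinite(beta))


class TestShrunkenLogistic:
    def test_unit_shrinkage_factor_is_identity(self, design):
        X, y = design
        beta = learners.fit_logistic_irls(X, y)
        literal = learners.apply_shrinkage(beta, 1.0, X, y, mode="literal")
        assert np.array_equal(literal, beta)
        default = learners.apply_shrinkage(beta, 1.0, X, y, mode="default")
        # slopes untouched; re-estimated intercept solves the same score equation
        assert np.array_equal(default[1:], beta[1:])
        assert default[0] == pytest.approx(beta[0], abs=1e-7)

    def test_modes_share_slopes_differ_in_intercept_handling(self, design):
        X, y = design
        sub = slice(0, 400)
        a = ts.fit_shrunken_logistic(X[sub], y[sub], B=30, seed=8, mode="default")
        b = ts.fit_shrunken_logistic(X[sub], y[sub], B=30, seed=8, mode="literal")
        assert np.array_equal(
            a.shrunken_coefficients[1:], b.shrunken_coefficients[1:]
        )
        assert b.shrunken_coefficients[0] == pytest.approx(
            b.shrinkage_factor * b.original_coefficients[0]
        )

    def test_shrinkage_factor_is_mean_of_bootstrap_slopes(self, design):
        X, y = design
        m = ts.fit_shrunken_logistic(X[:400], y[:400], B=25, seed=4)
        assert m.shrinkage_factor == pytest.approx(float(np.mean(m.bootstrap_slopes)))
        assert m.n_bootstrap == 25 and len(m.bootstrap_slopes) == 25

    def test_brute_force_reimplementation_oracle(self):
        """v_bar matches an independent step-by-step re-implementation to 1e-8.

        The oracle follows the documented resampling contract but fits every
        logistic model by direct minimization of the penalized deviance with
        scipy, independently of the package's Newton solver.
        """
        X, y = tiny_dataset(seed=5, n=60)
        B, seed = 50, 99

        def oracle_fit(Xf, yf, ridge):
            Xd = np.hstack([np.ones((len(yf), 1)), Xf])
            pen = np.r_[0.0, np.full(Xf.shape[1], ridge)]

            def nll(b):
                eta = Xd @ b
                return -np.sum(yf * eta - np.logaddexp(0, eta)) + 0.5 * np.sum(pen * b * b)

            def grad(b):
                return -(Xd.T @ (yf - expit(Xd @ b))) + pen * b

            res = minimize(nll, np.zeros(Xd.shape[1]), jac=grad, method="BFGS",
                           options={"gtol": 1e-12, "maxiter": 500})
            return res.x

        rng = np.random.default_rng(seed)
        slopes = []
        while len(slopes) < B:
            idx = rng.integers(0, len(y), len(y))
            if y[idx].min() == y[idx].max():
                continue
            bb = oracle_fit(X[idx], y[idx], learners.RIDGE_DEFAULT)
            lp = bb[0] + X @ bb[1:]
            slopes.append(oracle_fit(lp[:, None], y, learners.CALIBRATION_RIDGE)[1])
        expected_vbar = float(np.mean(slopes))

        model = ts.fit_shrunken_logistic(X, y, B=B, seed=seed)
        assert model.shrinkage_factor == pytest.approx(expected_vbar, abs=1e-8)

    def test_single_class_training_raises(self):
        X = np.zeros((10, 2))
        with pytest.raises(UnfittableError):
            ts.fit_shrunken_logistic(X, np.zeros(10, dtype=int), B=5, seed=0)

    def test_single_class_resamples_are_redrawn(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(8, 2)).astype(float)
        y = np.array([1, 0, 0, 0, 0, 0, 0, 0])
        m = ts.fit_shrunken_logistic(X, y, B=40, seed=1)
        assert m.n_redraws > 0
        assert len(m.bootstrap_slopes) == 40

    def test_small_sample_shrinks_below_one(self, design):
        """Overfitting in small samples pulls the median shrinkage factor below 1."""
        X, y = design
        rng = np.random.default_rng(12)
        vbars = []
        for _ in range(15):
            idx = rng.choice(len(y), 150, replace=False)
            if y[idx].min() == y[idx].max():
                continue
            vbars.append(
                ts.fit_shrunken_logistic(X[idx], y[idx], B=40, seed=int(rng.integers(2**31))).shrinkage_factor
            )
        assert np.median(vbars) < 1.0


class TestPredictProbability:
    def test_all_reference_row_is_logistic_of_intercept(self, design):
        X, y = design
        m = ts.fit_shrunken_logistic(X[:500], y[:500], B=10, seed=2)
        p = ts.predict_probability(m, np.zeros((1, X.shape[1])))
        assert p[0] == pytest.approx(expit(m.shrunken_coefficients[0]), abs=1e-12)

    def test_matches_hand_evaluated_logistic_formula(self, design):
        X, y = design
        m = ts.fit_shrunken_logistic(X[:500], y[:500], B=10, seed=2)
        rows = X[:7]
        beta = m.shrunken_coefficients
        expected = expit(beta[0] + rows @ beta[1:])
        assert np.allclose(ts.predict_probability(m, rows), expected, atol=1e-12)

    def test_row_order_invariance_and_bounds(self, design):
        X, y = design
        m = ts.fit_shrunken_logistic(X[:500], y[:500], B=10, seed=2)
        perm = np.random.default_rng(1).permutation(100)
        p = ts.predict_probability(m, X[:100])
        assert np.allclose(
            p[perm], ts.predict_probability(m, X[:100][perm]), rtol=0, atol=1e-12
        )
        assert np.all((p >= 0) & (p <= 1) & np.isfinite(p))

    def test_column_mismatch_raises_schema_error(self, design):
        X, y = design
        m = ts.fit_shrunken_logistic(X[:500], y[:500], B=5, seed=2)
        with pytest.raises(SchemaError):
            ts.predict_probability(m, X[:10, :7])


class TestBoostedTrees:
    def test_budget_one_selects_the_single_sampled_configuration(self, design):
        X, y = design
        m = ts.fit_boosted_trees(X[:400], y[:400], X[400:800], y[400:800],
                                 budget=1, seed=3)
        space = learners.SearchSpace()
        assert space.contains(m.tuned_hyperparameters)
        rng = np.random.default_rng(3)
        rng.integers(0, 2**31 - 1)  # fold seed drawn first
        rng.integers(0, 2**31 - 1)  # then the fit seed
        assert m.tuned_hyperparameters == space.sample(rng)

    def test_fixed_seed_reproduces_tuning_and_predictions(self, design):
        X, y = design
        fits = [
            ts.fit_boosted_trees(X[:400], y[:400], X[400:800], y[400:800],
                                 budget=3, seed=17)
            for _ in range(2)
        ]
        assert fits[0].tuned_hyperparameters == fits[1].tuned_hyperparameters
        p = [ts.predict_probability(m, X[800:900]) for m in fits]
        assert np.array_equal(p[0], p[1])

    def test_probabilities_in_unit_interval(self, design):
        X, y = design
        m = ts.fit_boosted_trees(X[:400], y[:400], X[400:800], y[400:800],
                                 budget=2, seed=5)
        p = ts.predict_probability(m, X)
        assert np.all((p >= 0) & (p <= 1) & np.isfinite(p))

    def test_single_class_pool_raises(self):
        X = np.zeros((20, 2))
        y = np.zeros(20, dtype=int)
        with pytest.raises(UnfittableError):
            ts.fit_boosted_trees(X, y, X, y, budget=1, seed=0)

    def test_competitive_discrimination_on_strong_signal(self):
        """With strong monotone effects the tuned booster's validation AUC is
        at least 90% of the shrunken-logistic AUC."""
        spec = ts.swetrau_like_spec(n_patients=10_000)
        df = ts.generate_cohort(spec, 61)
        X, y = ts.design_matrix(df)
        tr, va, te = slice(0, 4000), slice(4000, 7000), slice(7000, 10_000)
        lr = ts.fit_shrunken_logistic(X[tr], y[tr], B=30, seed=1)
        xgb = ts.fit_boosted_trees(X[tr], y[tr], X[va], y[va], budget=5, seed=1)
        auc_lr = ts.auc(ts.predict_probability(lr, X[te]), y[te])
        auc_xgb = ts.auc(ts.predict_probability(xgb, X[te]), y[te])
        assert auc_xgb >= 0.9 * auc_lr
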
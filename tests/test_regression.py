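"""From-scratch MLR and SGD: recovery, invariants, cross-library checks."""

import numpy as np
import pytest

from thermoforge.group_additivity import GroupVector, estimate_formation
from thermoforge.regression import (
    DivergenceError,
    FeatureTable,
    SgdConfig,
    evaluate,
    fit_and_evaluate,
    fit_mlr,
    fit_sgd,
    holdout_split,
    to_coefficient_table,
)
from thermoforge.synthetic import make_group_table

VOCAB = tuple(f"g{i}" for i in range(10))


def _standardized_gap(fit_a, fit_b, table):
    x_sd = table.X.std(axis=0)
    y_sd = table.y.std()
    return np.max(np.abs((fit_a.coefficients - fit_b.coefficients) * x_sd / y_sd))


class TestMlr:
    def test_noiseless_recovery(self):
        table, truth = make_group_table(VOCAB, n=80, noise_sd=0.0, seed=1)
        fit = fit_mlr(table)
        assert np.allclose(fit.coefficients, truth.coefficients, atol=1e-8)
        assert fit.intercept == pytest.approx(truth.intercept, abs=1e-8)
        assert evaluate(table.y, fit.predict(table.X)).r2 == pytest.approx(1.0)

    def test_two_point_line_closed_form(self):
        table = FeatureTable(("a", "b"), ("x",), np.array([[1.0], [3.0]]), np.array([2.0, 8.0]))
        fit = fit_mlr(table)
        # hand-computed two-point line: slope 3, intercept -1
        assert fit.coefficients[0] == pytest.approx(3.0)
        assert fit.intercept == pytest.approx(-1.0)

    def test_noisy_recovery_within_three_se(self):
        table, truth = make_group_table(VOCAB, n=80, noise_sd=2.0, seed=42)
        fit = fit_mlr(table)
        A = np.column_stack([np.ones(80), table.X])
        se = truth.noise_sd * np.sqrt(np.diag(np.linalg.inv(A.T @ A)))
        est = np.concatenate([[fit.intercept], fit.coefficients])
        tru = np.concatenate([[truth.intercept], truth.coefficients])
        assert np.all(np.abs(est - tru) <= 3 * se)

    def test_residuals_orthogonal_to_design(self):
        table, _ = make_group_table(VOCAB, n=60, noise_sd=3.0, seed=9)
        fit = fit_mlr(table)
        residuals = table.y - fit.predict(table.X)
        assert np.max(np.abs(table.X.T @ residuals)) < 1e-6 * np.linalg.norm(table.y)

    def test_rank_deficient_warns_minimum_norm(self):
        X = np.column_stack([np.arange(6.0), 2 * np.arange(6.0)])  # collinear
        table = FeatureTable(tuple("abcdef"), ("x1", "x2"), X, np.arange(6.0))
        with pytest.warns(UserWarning, match="rank-deficient"):
            fit = fit_mlr(table)
        assert fit.rank_deficient
        assert np.allclose(fit.predict(X), table.y, atol=1e-8)


class TestSgd:
    def test_matches_mlr_on_full_rank_table(self):
        table, _ = make_group_table(VOCAB, n=84, noise_sd=0.0, seed=3)
        mlr = fit_mlr(table)
        sgd = fit_sgd(table, SgdConfig(epochs=1000, seed=3))
        assert _standardized_gap(sgd, mlr, table) < 1e-3

    def test_zero_learning_rate_keeps_initialization(self):
        table, _ = make_group_table(VOCAB, n=30, noise_sd=1.0, seed=4)
        fit = fit_sgd(table, SgdConfig(learning_rate=0.0, epochs=5, seed=0))
        assert np.allclose(fit.coefficients, 0.0)

    def test_fixed_seed_bit_identical(self):
        table, _ = make_group_table(VOCAB, n=40, noise_sd=1.0, seed=6)
        cfg = SgdConfig(epochs=50, seed=7)
        a = fit_sgd(table, cfg)
        b = fit_sgd(table, cfg)
        assert np.array_equal(a.coefficients, b.coefficients)
        assert np.array_equal(a.loss_history, b.loss_history)
        assert a.intercept == b.intercept

    def test_divergence_error_names_learning_rate(self):
        table, _ = make_group_table(VOCAB, n=40, noise_sd=1.0, seed=6)
        with pytest.raises(DivergenceError, match="learning rate"):
            fit_sgd(table, SgdConfig(learning_rate=1.5, epochs=50, seed=0))


class TestHoldout:
    def test_seventy_thirty_counts(self):
        split = holdout_split(10, fraction=0.7, seed=1)
        assert len(split.train_indices) == 7 and len(split.test_indices) == 3
        assert set(split.train_indices) | set(split.test_indices) == set(range(10))
        assert not set(split.train_indices) & set(split.test_indices)

    def test_ceiling_convention_on_84(self):
        split = holdout_split(84, fraction=0.7, seed=204)
        assert len(split.train_indices) == 59 and len(split.test_indices) == 25

    def test_seed_determinism_and_variation(self):
        a = holdout_split(50, seed=12)
        b = holdout_split(50, seed=12)
        assert np.array_equal(a.train_indices, b.train_indices)
        distinct = sum(
            not np.array_equal(
                holdout_split(50, seed=s).train_indices,
                holdout_split(50, seed=s + 1).train_indices,
            )
            for s in range(100)
        )
        assert distinct >= 95

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            holdout_split(1)
        with pytest.raises(ValueError):
            holdout_split(10, fraction=1.0)


class TestEvaluate:
    def test_perfect_and_null_predictions(self):
        y = np.array([1.0, 2.0, 4.0, 7.0])
        assert evaluate(y, y) == pytest.approx((1.0, 0.0, 0.0))
        assert evaluate(y, np.full(4, y.mean())).r2 == pytest.approx(0.0)

    def test_matches_sklearn_oracle(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(8)
        y_true = rng.normal(size=50)
        y_pred = y_true + rng.normal(0, 0.3, size=50)
        m = evaluate(y_true, y_pred)
        assert m.r2 == pytest.approx(sklearn_metrics.r2_score(y_true, y_pred), rel=1e-10)
        assert m.mae == pytest.approx(
            sklearn_metrics.mean_absolute_error(y_true, y_pred), rel=1e-10
        )
        assert m.rmse == pytest.approx(
            np.sqrt(sklearn_metrics.mean_squared_error(y_true, y_pred)), rel=1e-10
        )

    def test_rmse_never_below_mae(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            y = rng.normal(size=30)
            p = y + rng.normal(0, rng.uniform(0.1, 2.0), size=30)
            m = evaluate(y, p)
            assert m.rmse >= m.mae

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            evaluate(np.ones(5), np.arange(5.0))


class TestWorkflowAndRoundTrip:
    def test_holdout_workflow_reports_both_metric_sets(self):
        table, _ = make_group_table(VOCAB, n=84, noise_sd=2.0, seed=204)
        fit = fit_and_evaluate(table, method="mlr", seed=204)
        assert fit.train_metrics.r2 > 0.99
        assert fit.test_metrics is not None and fit.test_metrics.r2 <= 1.0

    def test_coefficient_table_round_trip_reproduces_predictions(self):
        table, _ = make_group_table(VOCAB, n=40, noise_sd=1.0, seed=11)
        fit = fit_mlr(table)
        coeff_table = to_coefficient_table(fit)
        for i in range(5):
            vec = GroupVector(
                table.compound_ids[i], dict(zip(table.feature_names, table.X[i]))
            )
            additive = estimate_formation(vec, coeff_table)
            assert additive == pytest.approx(float(fit.predict(table.X[i : i + 1])[0]), rel=1e-12)
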
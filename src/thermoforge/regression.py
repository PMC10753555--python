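"""Linear regression over group-count feature tables.

Two estimators of the same linear-additive model are provided, both
written here rather than delegated, since the estimators are the object
of study:

* :func:`fit_mlr` — ordinary least squares with intercept, solved by a
  rank-revealing least-squares factorization (minimum-norm solution with
  a warning when the design is rank deficient);
* :func:`fit_sgd` — stochastic gradient descent on the squared loss, one
  example at a time with per-epoch reshuffling, inverse-scaling learning
  rate, and optional feature standardization (on by default — SGD on raw
  group counts is badly conditioned).

Evaluation uses seeded 70/30 hold-out splitting and the usual trio of
metrics (R^2, MAE, RMSE).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil
from typing import NamedTuple, Sequence

import numpy as np

from .group_additivity import CoefficientTable

__all__ = [
    "FeatureTable",
    "HoldoutSplit",
    "RegressionFit",
    "SgdConfig",
    "Metrics",
    "DivergenceError",
    "fit_mlr",
    "fit_sgd",
    "holdout_split",
    "evaluate",
    "fit_and_evaluate",
    "to_coefficient_table",
]


class DivergenceError(RuntimeError):
    """SGD loss blew up; the learning rate is named in the message."""


@dataclass(frozen=True)
class FeatureTable:
    """Design matrix of group counts plus a target vector.

    ``X`` has one row per compound and one column per group; ``y`` holds
    the targets (conventionally -dfH(g) in kJ mol^-1).
    """

    compound_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "compound_ids", tuple(self.compound_ids))
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y row counts differ")
        if len(self.compound_ids) != X.shape[0]:
            raise ValueError("compound_ids length must match rows of X")
        if len(self.feature_names) != X.shape[1]:
            raise ValueError("feature_names length must match columns of X")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("missing or non-finite entries are not allowed")

    def subset(self, indices: Sequence[int]) -> "FeatureTable":
        idx = np.asarray(indices, dtype=int)
        return FeatureTable(
            compound_ids=tuple(self.compound_ids[i] for i in idx),
            feature_names=self.feature_names,
            X=self.X[idx],
            y=self.y[idx],
        )


@dataclass(frozen=True)
class HoldoutSplit:
    n: int
    train_fraction: float
    seed: int
    train_indices: np.ndarray
    test_indices: np.ndarray


class Metrics(NamedTuple):
    r2: float
    mae: float
    rmse: float


@dataclass
class SgdConfig:
    """Plain SGD hyperparameters.

    The learning rate follows an inverse-scaling schedule
    ``eta_t = eta0 / (1 + eta0 * decay * t)`` with ``t`` counting single-
    example updates; ``tol`` stops training when the epoch-mean loss
    improves by less than ``tol`` (absolute).
    """

    learning_rate: float = 0.01
    decay: float = 1e-4
    epochs: int = 1000
    seed: int = 0
    tol: float = 0.0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass(frozen=True)
class RegressionFit:
    method: str
    intercept: float
    coefficients: np.ndarray
    feature_names: tuple[str, ...]
    rank_deficient: bool = False
    train_metrics: Metrics | None = None
    test_metrics: Metrics | None = None
    loss_history: np.ndarray | None = None

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept + X @ self.coefficients


def fit_mlr(table: FeatureTable) -> RegressionFit:
    """Ordinary least squares with intercept.

    Solves ``min ||[1 X] b - y||`` via numpy's SVD-based lstsq. When the
    augmented design has deficient column rank (including the
    underdetermined n_rows < n_features + 1 case) the minimum-norm
    solution is returned and a warning is emitted.
    """
    n, p = table.X.shape
    A = np.column_stack([np.ones(n), table.X])
    beta, _, rank, _ = np.linalg.lstsq(A, table.y, rcond=None)
    deficient = rank < p + 1
    if deficient:
        warnings.warn(
            "rank-deficient design: returning the minimum-norm least-squares solution",
            stacklevel=2,
        )
    return RegressionFit(
        method="MLR",
        intercept=float(beta[0]),
        coefficients=beta[1:],
        feature_names=table.feature_names,
        rank_deficient=deficient,
    )


def fit_sgd(table: FeatureTable, config: SgdConfig | None = None) -> RegressionFit:
    """Stochastic gradient descent on the squared loss.

    One parameter update per training example, examples reshuffled every
    epoch from the config seed. Coefficients are learned in standardized
    feature/target units when ``config.standardize`` (recommended) and
    mapped back to the original scale afterwards. Raises
    :class:`DivergenceError` if the epoch-mean loss grows 10-fold.
    """
    config = config or SgdConfig()
    X, y = table.X, table.y
    n, p = X.shape

    if config.standardize:
        x_mean, x_sd = X.mean(axis=0), X.std(axis=0)
        x_sd = np.where(x_sd == 0, 1.0, x_sd)
        y_mean, y_sd = y.mean(), y.std() or 1.0
        Xs = (X - x_mean) / x_sd
        ys = (y - y_mean) / y_sd
    else:
        x_mean = np.zeros(p)
        x_sd = np.ones(p)
        y_mean, y_sd = 0.0, 1.0
        Xs, ys = X, y

    w = np.zeros(p)
    b = 0.0
    rng = np.random.default_rng(config.seed)
    eta0 = config.learning_rate
    t = 0
    history = np.empty(config.epochs)
    prev_loss = np.inf
    n_epochs_run = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for i in order:
            eta = eta0 / (1.0 + eta0 * config.decay * t)
            err = (b + Xs[i] @ w) - ys[i]
            b -= eta * err
            w -= eta * err * Xs[i]
            t += 1
        residuals = ys - (b + Xs @ w)
        loss = float(np.mean(residuals**2))
        history[epoch] = loss
        n_epochs_run = epoch + 1
        if np.isfinite(prev_loss) and loss > 10.0 * prev_loss:
            raise DivergenceError(
                f"SGD diverged at epoch {epoch} (learning rate {eta0})"
            )
        if config.tol > 0 and abs(prev_loss - loss) < config.tol:
            break
        prev_loss = loss

    coefficients = y_sd * w / x_sd
    intercept = y_mean + y_sd * b - float(coefficients @ x_mean)
    return RegressionFit(
        method="SGD",
        intercept=intercept,
        coefficients=coefficients,
        feature_names=table.feature_names,
        loss_history=history[:n_epochs_run],
    )


def holdout_split(n: int, fraction: float = 0.7, seed: int = 0) -> HoldoutSplit:
    """Seeded permutation split; the first ceil(fraction*n) indices train."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if n < 2:
        raise ValueError("need at least two rows to split")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = ceil(fraction * n)
    return HoldoutSplit(
        n=n,
        train_fraction=fraction,
        seed=seed,
        train_indices=perm[:n_train],
        test_indices=perm[n_train:],
    )


def evaluate(y_true, y_pred) -> Metrics:
    """R^2 = 1 - SS_res/SS_tot, mean absolute error, root mean squared error."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("need two equal-length vectors of at least 2 entries")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: y_true has zero variance")
    err = y_true - y_pred
    return Metrics(
        r2=1.0 - float(np.sum(err**2)) / ss_tot,
        mae=float(np.mean(np.abs(err))),
        rmse=float(np.sqrt(np.mean(err**2))),
    )


def fit_and_evaluate(
    table: FeatureTable,
    method: str = "mlr",
    fraction: float = 0.7,
    seed: int = 0,
    sgd_config: SgdConfig | None = None,
) -> RegressionFit:
    """Hold-out workflow: split, fit on train, score on both parts."""
    split = holdout_split(len(table.y), fraction=fraction, seed=seed)
    train = table.subset(split.train_indices)
    test = table.subset(split.test_indices)
    if method.lower() == "mlr":
        fit = fit_mlr(train)
    elif method.lower() == "sgd":
        fit = fit_sgd(train, sgd_config)
    else:
        raise ValueError(f"unknown method {method!r}")
    train_m = evaluate(train.y, fit.predict(train.X))
    test_m = evaluate(test.y, fit.predict(test.X)) if len(test.y) >= 2 else None
    return RegressionFit(
        method=fit.method,
        intercept=fit.intercept,
        coefficients=fit.coefficients,
        feature_names=fit.feature_names,
        rank_deficient=fit.rank_deficient,
        train_metrics=train_m,
        test_metrics=test_m,
        loss_history=fit.loss_history,
    )


def to_coefficient_table(fit: RegressionFit) -> CoefficientTable:
    """Export fitted coefficients as an additive coefficient table, so a
    fit can be consumed by the group-additivity estimator unchanged."""
    return CoefficientTable(
        intercept=fit.intercept,
        values=dict(zip(fit.feature_names, (float(c) for c in fit.coefficients))),
    )
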
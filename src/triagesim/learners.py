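"""The two triage learners behind a common fit / predict-probability contract.

Logistic regression with bootstrap uniform shrinkage
----------------------------------------------------
The original model ``M0`` is fitted by penalized maximum likelihood (a tiny
ridge ``1e-4`` on the slopes keeps rare, outcome-pure categories finite; the
intercept is never penalized).  For each of ``B`` bootstrap replicates a
same-size resample of the training set is fitted, its linear predictor is
evaluated on the *original* training set, and the training outcomes are
regressed on that linear predictor with a two-parameter logistic
recalibration; the slope ``b_i`` measures how much the replicate overfits.
The shrinkage factor ``v_bar = mean(b_i)`` scales the slopes of ``M0``
("uniform shrinkage").  In the default mode the intercept is then re-estimated
with the shrunken linear predictor as offset, preserving calibration-in-the-
large; the literal mode instead multiplies every coefficient, intercept
included, by ``v_bar``.

Gradient-boosted trees
----------------------
XGBoost with a binary logistic objective.  ``n_estimators`` (boosting rounds),
``learning_rate``, ``max_depth`` and the L2 penalty ``reg_lambda`` are tuned
by random search with stratified five-fold cross-validation on the pooled
training + validation data, scored by mean held-out log-loss; the winning
configuration is refitted on the training set only.

Bootstrap resampling contract (documented so independent re-implementations
can reproduce it): with ``rng = numpy.random.default_rng(seed)``, replicate
indices are drawn sequentially as ``rng.integers(0, n, n)``; a single-class
resample is discarded and redrawn from the same stream, with a hard cap of
``10 * B`` total draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

from .exceptions import SchemaError, UnfittableError

RIDGE_DEFAULT = 1e-4  # on slopes of the main fit
CALIBRATION_RIDGE = 1e-6  # on the recalibration slope (guards separation)


def fit_logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = RIDGE_DEFAULT,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> np.ndarray:
    """Ridge-penalized logistic MLE by Newton-Raphson with step halving.

    Returns ``[intercept, slopes...]``.  The penalty ``0.5 * ridge * ||slopes||^2``
    excludes the intercept.  Columns that are identically zero get coefficient
    exactly 0 (the penalty is their only gradient contribution).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    Xd = np.hstack([np.ones((n, 1)), X])
    pen = np.full(p + 1, ridge)
    pen[0] = 0.0
    beta = np.zeros(p + 1)

    def objective(b):
        eta = Xd @ b
        # -loglik + penalty, computed stably
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        return -ll + 0.5 * float(np.sum(pen * b * b))

    obj = objective(beta)
    for _ in range(max_iter):
        eta = Xd @ beta
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        grad = Xd.T @ (y - mu) - pen * beta
        H = (Xd.T * w) @ Xd + np.diag(pen + 1e-12)
        step = np.linalg.solve(H, grad)
        # step halving to guarantee monotone descent of the penalized deviance
        t = 1.0
        for _ in range(50):
            cand = beta + t * step
            cand_obj = objective(cand)
            if cand_obj <= obj + 1e-14:
                break
            t *= 0.5
        beta, obj = cand, cand_obj
        if float(np.max(np.abs(t * step))) < tol:
            break
    return beta


def _refit_intercept(offset: np.ndarray, y: np.ndarray) -> float:
    """MLE intercept of a logistic model with fixed offset (slope pinned at 1)."""
    ybar = float(np.mean(y))

    def score(a: float) -> float:
        return float(np.sum(y - expit(a + offset)))

    # bracket wide enough that every fitted probability saturates at the ends
    lo = float(-np.max(offset) - 50.0)
    hi = float(-np.min(offset) + 50.0)
    if not (score(lo) > 0 > score(hi)):  # cannot happen for 0 < ybar < 1
        raise UnfittableError(f"intercept refit failed (mean outcome {ybar})")
    return float(brentq(score, lo, hi, xtol=1e-12))


@dataclass
class ShrunkenLogisticModel:
    """Logistic model with bootstrap uniform shrinkage applied."""

    original_coefficients: np.ndarray  # [intercept, 11 slopes]
    bootstrap_slopes: np.ndarray
    shrinkage_factor: float
    shrunken_coefficients: np.ndarray
    n_bootstrap: int
    mode: str = "default"
    n_features: int = 11
    n_redraws: int = 0

    def to_dict(self) -> dict[str, Any]:
        b = self.bootstrap_slopes
        return {
            "original_coefficients": self.original_coefficients.tolist(),
            "shrunken_coefficients": self.shrunken_coefficients.tolist(),
            "shrinkage_factor": self.shrinkage_factor,
            "n_bootstrap": self.n_bootstrap,
            "mode": self.mode,
            "bootstrap_slopes_summary": {
                "mean": float(np.mean(b)),
                "min": float(np.min(b)),
                "max": float(np.max(b)),
            },
            "n_redraws": self.n_redraws,
        }


def apply_shrinkage(
    coefficients: np.ndarray,
    shrinkage_factor: float,
    X: np.ndarray,
    y: np.ndarray,
    mode: str = "default",
) -> np.ndarray:
    """Scale slopes by the shrinkage factor.

    ``default``: slopes are multiplied by the factor and the intercept is
    re-estimated against the training outcomes with the shrunken linear
    predictor as offset.  ``literal``: every coefficient, intercept included,
    is multiplied by the factor.
    """
    coefficients = np.asarray(coefficients, dtype=np.float64)
    if mode == "literal":
        return shrinkage_factor * coefficients
    if mode != "default":
        raise ValueError(f"unknown shrinkage mode {mode!r}")
    shrunk = coefficients.copy()
    shrunk[1:] *= shrinkage_factor
    offset = np.asarray(X, dtype=np.float64) @ shrunk[1:]
    shrunk[0] = _refit_intercept(offset, np.asarray(y, dtype=np.float64))
    return shrunk


def fit_shrunken_logistic(
    X: np.ndarray,
    y: np.ndarray,
    B: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    ridge: float = RIDGE_DEFAULT,
    mode: str = "default",
) -> ShrunkenLogisticModel:
    """Fit the bootstrap-shrunken logistic regression (see module docstring)."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if B < 1:
        raise ValueError("B must be >= 1")
    classes = np.unique(y)
    if classes.size < 2:
        raise UnfittableError("training outcome has a single class")

    n = len(y)
    original = fit_logistic_irls(X, y, ridge=ridge)

    rng = np.random.default_rng(seed)
    slopes = np.empty(B)
    draws = 0
    redraws = 0
    i = 0
    while i < B:
        if draws >= 10 * B:
            raise UnfittableError(
                f"exceeded {10 * B} bootstrap draws without {B} two-class resamples"
            )
        idx = rng.integers(0, n, n)
        draws += 1
        yb = y[idx]
        if yb.min() == yb.max():
            redraws += 1
            continue
        beta_b = fit_logistic_irls(X[idx], yb, ridge=ridge)
        lp = beta_b[0] + X @ beta_b[1:]
        recal = fit_logistic_irls(lp[:, None], y, ridge=CALIBRATION_RIDGE)
        slopes[i] = recal[1]
        i += 1

    v_bar = float(np.mean(slopes))
    shrunken = apply_shrinkage(original, v_bar, X, y, mode=mode)
    return ShrunkenLogisticModel(
        original_coefficients=original,
        bootstrap_slopes=slopes,
        shrinkage_factor=v_bar,
        shrunken_coefficients=shrunken,
        n_bootstrap=B,
        mode=mode,
        n_features=X.shape[1],
        n_redraws=redraws,
    )


# ---------------------------------------------------------------------------
# Gradient-boosted trees


@dataclass(frozen=True)
class SearchSpace:
    """Random-search ranges for the tuned hyperparameters (log-uniform except
    depth)."""

    boosting_rounds: tuple[int, int] = (10, 500)
    learning_rate: tuple[float, float] = (0.01, 0.3)
    max_tree_depth: tuple[int, int] = (1, 6)
    l2_regularization: tuple[float, float] = (0.1, 10.0)

    def sample(self, rng: np.random.Generator) -> dict[str, float | int]:
        lo, hi = self.boosting_rounds
        rounds = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
        lo, hi = self.learning_rate
        eta = float(math.exp(rng.uniform(math.log(lo), math.log(hi))))
        depth = int(rng.integers(self.max_tree_depth[0], self.max_tree_depth[1] + 1))
        lo, hi = self.l2_regularization
        lam = float(math.exp(rng.uniform(math.log(lo), math.log(hi))))
        return {
            "boosting_rounds": rounds,
            "learning_rate": eta,
            "max_tree_depth": depth,
            "l2_regularization": lam,
        }

    def contains(self, params: dict[str, float | int]) -> bool:
        return (
            self.boosting_rounds[0] <= params["boosting_rounds"] <= self.boosting_rounds[1]
            and self.learning_rate[0] <= params["learning_rate"] <= self.learning_rate[1]
            and self.max_tree_depth[0] <= params["max_tree_depth"] <= self.max_tree_depth[1]
            and self.l2_regularization[0]
            <= params["l2_regularization"]
            <= self.l2_regularization[1]
        )


@dataclass
class BoostedTreesModel:
    """Tuned gradient-boosted trees learner."""

    tuned_hyperparameters: dict[str, float | int]
    search_budget: int
    cv_folds: int
    fitted_model: Any
    n_features: int = 11
    cv_score: float = float("nan")
    scoring: str = "logloss"

    def hyperparameters_sidecar(self) -> dict[str, Any]:
        return {
            "tuned_hyperparameters": self.tuned_hyperparameters,
            "search_budget": self.search_budget,
            "cv_folds": self.cv_folds,
            "cv_score": self.cv_score,
            "scoring": self.scoring,
        }


def _make_booster(params: dict[str, float | int], seed: int) -> XGBClassifier:
    return XGBClassifier(
        n_estimators=int(params["boosting_rounds"]),
        learning_rate=float(params["learning_rate"]),
        max_depth=int(params["max_tree_depth"]),
        reg_lambda=float(params["l2_regularization"]),
        objective="binary:logistic",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        verbosity=0,
    )


def fit_boosted_trees(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_validation: np.ndarray,
    y_validation: np.ndarray,
    budget: int = 30,
    seed: int | np.random.SeedSequence = 0,
    cv_folds: int = 5,
    space: SearchSpace = SearchSpace(),
    scoring: str = "logloss",
) -> BoostedTreesModel:
    """Random-search tuning on pooled train+validation, final fit on train only."""
    if budget < 1:
        raise ValueError("budget must be >= 1")
    X_train = np.asarray(X_train, dtype=np.float64)
    X_validation = np.asarray(X_validation, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=np.int64)
    y_validation = np.asarray(y_validation, dtype=np.int64)
    X_pool = np.vstack([X_train, X_validation])
    y_pool = np.concatenate([y_train, y_validation])
    if np.unique(y_pool).size < 2:
        raise UnfittableError("pooled tuning data has a single class")
    if np.unique(y_train).size < 2:
        raise UnfittableError("training outcome has a single class")

    rng = np.random.default_rng(seed)
    fold_seed = int(rng.integers(0, 2**31 - 1))
    fit_seed = int(rng.integers(0, 2**31 - 1))
    splitter = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=fold_seed)
    folds = list(splitter.split(X_pool, y_pool))

    best_params: dict[str, float | int] | None = None
    best_score = np.inf
    for _ in range(budget):
        params = space.sample(rng)
        scores = []
        for tr, te in folds:
            clf = _make_booster(params, fit_seed)
            clf.fit(X_pool[tr], y_pool[tr])
            prob = clf.predict_proba(X_pool[te])[:, 1]
            if scoring == "logloss":
                scores.append(log_loss(y_pool[te], prob, labels=[0, 1]))
            elif scoring == "error":
                scores.append(float(np.mean((prob >= 0.5) != y_pool[te])))
            else:
                raise ValueError(f"unknown scoring {scoring!r}")
        score = float(np.mean(scores))
        if score < best_score:
            best_score, best_params = score, params

    assert best_params is not None
    final = _make_booster(best_params, fit_seed)
    final.fit(X_train, y_train)
    return BoostedTreesModel(
        tuned_hyperparameters=best_params,
        search_budget=budget,
        cv_folds=cv_folds,
        fitted_model=final,
        n_features=X_train.shape[1],
        cv_score=best_score,
        scoring=scoring,
    )


def predict_probability(
    model: ShrunkenLogisticModel | BoostedTreesModel, X: np.ndarray
) -> np.ndarray:
    """Per-row probability of major trauma under either learner."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise SchemaError(
            f"expected {model.n_features} feature columns, got {X.shape[1] if X.ndim == 2 else 'non-2d'}"
        )
    if isinstance(model, ShrunkenLogisticModel):
        beta = model.shrunken_coefficients
        return expit(beta[0] + X @ beta[1:])
    if isinstance(model, BoostedTreesModel):
        return model.fitted_model.predict_proba(X)[:, 1].astype(np.float64)
    raise TypeError(f"unsupported model type {type(model)!r}")
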
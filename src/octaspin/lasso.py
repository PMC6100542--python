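"""L1-regularized linear regression for descriptor-set comparison.

The linear model y = beta^T x + beta0 is fitted by minimizing

    (1 / 2n) * sum_i (y_i - beta^T x_i - beta0)^2 + lambda * ||beta||_1

with an unpenalized intercept (scikit-learn's Lasso convention; equivalent
to glmnet up to the same 1/2n scaling). The penalty weight lambda is chosen
by k-fold cross-validation over a log-spaced grid, optionally stratified by
a class label (metal identity) so small classes are spread across folds.

The linear model is not the production predictor — it ranks candidate
descriptor sets (a-g) by cross-validated RMSE before the network is trained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.linear_model import Lasso, LinearRegression
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "LassoFit",
    "lasso_fit",
    "lambda_max",
    "cv_select_lambda",
    "default_lambda_grid",
    "rmse",
    "compare_sets",
]


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Prediction root-mean-squared error sqrt(mean((y - yhat)^2))."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch {y_true.shape} vs {y_pred.shape}")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


@dataclass
class LassoFit:
    beta: np.ndarray
    beta0: float
    lam: float
    active_set: np.ndarray  # column indices with beta != 0
    cv_curve: list[tuple[float, float]] | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.beta + self.beta0


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty for which the solution is all-zero: ||X^T(y - ybar)||_inf / n."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.max(np.abs(X.T @ (y - y.mean()))) / len(y))


def lasso_fit(X: np.ndarray, y: np.ndarray, lam: float) -> LassoFit:
    """Fit the L1-penalized least-squares model at a fixed penalty.

    ``lam = 0`` reduces to ordinary least squares. The fit is deterministic
    given the data and penalty.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("design matrix must be 2-D with at least one row")
    if X.shape[0] != len(y):
        raise ValueError(f"{X.shape[0]} rows but {len(y)} targets")
    if lam < 0:
        raise ValueError("penalty must be non-negative")
    if lam == 0:
        ols = LinearRegression().fit(X, y)
        beta, beta0 = ols.coef_, float(ols.intercept_)
    else:
        model = Lasso(alpha=lam, fit_intercept=True, max_iter=100_000, tol=1e-10)
        model.fit(X, y)
        beta, beta0 = model.coef_, float(model.intercept_)
    active = np.flatnonzero(beta)
    return LassoFit(beta=np.asarray(beta, dtype=float), beta0=beta0, lam=lam, active_set=active)


def default_lambda_grid(n_points: int = 50) -> np.ndarray:
    """Log-spaced penalty grid over [1e-6, 1e-1]."""
    return np.logspace(-6, -1, n_points)


def cv_select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    grid: Sequence[float] | None = None,
    folds: int = 10,
    seed: int = 0,
    stratify: Sequence | None = None,
) -> tuple[float, list[tuple[float, float]]]:
    """Select the penalty minimizing mean out-of-fold squared error.

    Fold assignment is reproducible from ``seed``; with ``stratify`` given
    (e.g. metal identity per row) folds are stratified so every class
    appears in each fold where possible.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if folds > n:
        raise ValueError(f"{folds} folds but only {n} rows")
    if grid is None:
        grid = default_lambda_grid()
    grid = sorted(float(g) for g in grid)
    if stratify is not None:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = list(splitter.split(X, np.asarray(stratify)))
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = list(splitter.split(X))
    curve: list[tuple[float, float]] = []
    for lam in grid:
        errs = []
        for train_idx, test_idx in split_iter:
            fit = lasso_fit(X[train_idx], y[train_idx], lam)
            resid = y[test_idx] - fit.predict(X[test_idx])
            errs.append(float(np.mean(resid**2)))
        curve.append((lam, float(np.mean(errs))))
    best_lam = min(curve, key=lambda t: t[1])[0]
    return best_lam, curve


def cv_lasso(
    X: np.ndarray,
    y: np.ndarray,
    grid: Sequence[float] | None = None,
    folds: int = 10,
    seed: int = 0,
    stratify: Sequence | None = None,
) -> LassoFit:
    """CV-select the penalty, then refit on the full data."""
    lam, curve = cv_select_lambda(X, y, grid=grid, folds=folds, seed=seed, stratify=stratify)
    fit = lasso_fit(X, y, lam)
    fit.cv_curve = curve
    return fit


def _cv_rmse(
    X: np.ndarray, y: np.ndarray, lam: float, folds: int, seed: int, stratify
) -> float:
    """Out-of-fold RMSE at a fixed penalty."""
    if stratify is not None:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(X, np.asarray(stratify))
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(X)
    sq = []
    for train_idx, test_idx in split_iter:
        fit = lasso_fit(X[train_idx], y[train_idx], lam)
        sq.extend(((y[test_idx] - fit.predict(X[test_idx])) ** 2).tolist())
    return float(np.sqrt(np.mean(sq)))


def compare_sets(
    dataset,
    sets: Sequence[str] = ("a", "b", "c", "d", "e", "f", "g"),
    targets: Sequence[str] = ("splitting", "sensitivity"),
    grid: Sequence[float] | None = None,
    folds: int = 10,
    seed: int = 0,
):
    """Cross-validated RMSE of the penalized linear model per (descriptor set, target).

    ``dataset`` is a :class:`octaspin.io.DatasetTable`. The reported RMSE is
    the out-of-fold error at the CV-selected penalty (labelled ``cv_rmse``);
    discrete/continuous variable counts (with total binary levels) accompany
    each row, mirroring the descriptor-set comparison layout.
    """
    import pandas as pd

    from .encoding import encode
    from .io import extract_target

    rows = []
    for set_id in sets:
        for target in targets:
            specs, y = extract_target(dataset, target)
            include_a_hf = target != "sensitivity"
            from .descriptors import featurize_many

            vectors = featurize_many(specs, set_id=set_id, include_a_hf=include_a_hf)
            X, meta = encode(vectors, mode="lasso")
            metals = [s.metal for s in specs]
            lam, _ = cv_select_lambda(
                X, y, grid=grid, folds=folds, seed=seed, stratify=metals
            )
            err = _cv_rmse(X, y, lam, folds, seed, metals)
            n_disc = len(meta.categorical)
            n_levels = sum(len(meta.levels[c]) for c in meta.categorical)
            n_cont = len(meta.feature_names) - n_disc
            rows.append(
                {
                    "set": set_id,
                    "target": target,
                    "cv_rmse": err,
                    "lambda": lam,
                    "discrete_vars": n_disc,
                    "discrete_levels": n_levels,
                    "continuous_vars": n_cont,
                    "n": len(y),
                }
            )
    return pd.DataFrame(rows)
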
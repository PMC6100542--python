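"""Monte-Carlo dropout uncertainty quantification.

Minimizing the dropout + L2 loss is an approximate variational optimization
of a deep Gaussian process, so sampling J networks with independently
dropped nodes at the optimized weights yields a principled predictive
distribution. For a query x:

    mean(x)     = (1/J) sum_j yhat_j(x)
    var(x)      = 1/tau + (1/J) sum_j yhat_j(x)^2 - mean(x)^2

where 1/tau is the baseline (irreducible) variance inherent in the data and
the second term the spread of the GP itself. The precision follows the
dropout-GP correspondence

    tau = p_keep * l^2 / (2 * N * lambda)

with N the number of training points, lambda the L2 penalty weight, p_keep
the keep probability and l the GP length-scale hyperparameter. l does not
enter training; it is chosen by maximizing the Gaussian log predictive
likelihood of held-out training data under the MC-dropout mean/variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ann import TrainedModel, forward

__all__ = [
    "UQResult",
    "mc_dropout_predict",
    "compute_tau",
    "select_length_scale",
    "coverage_report",
]


@dataclass
class UQResult:
    """Per-query predictive mean and variance from J dropout realizations."""

    mean: np.ndarray  # (n, n_out) in target units
    variance: np.ndarray  # (n, n_out) in target units squared
    J: int
    tau: float

    @property
    def std(self) -> np.ndarray:
        return np.sqrt(self.variance)


def compute_tau(n_train: int, lam: float, p_drop: float, l_scale: float) -> float:
    """Model precision tau = p_keep * l^2 / (2 * N * lambda)."""
    if n_train <= 0 or l_scale <= 0:
        raise ValueError("n_train and l_scale must be positive")
    if not 0 <= p_drop < 1:
        raise ValueError("p_drop must lie in [0, 1)")
    if lam <= 0:
        raise ValueError(
            "tau is undefined for a zero L2 penalty (the GP correspondence "
            "requires lambda > 0)"
        )
    return (1.0 - p_drop) * l_scale**2 / (2.0 * n_train * lam)


def mc_dropout_predict(
    model: TrainedModel,
    X: np.ndarray,
    J: int = 100,
    seed: int = 0,
    tau: float | None = None,
) -> UQResult:
    """Predictive mean and variance from J seeded dropout masks at fixed weights.

    ``X`` is an encoded design matrix (use the model's encoding meta). With
    ``p_drop = 0`` every realization is identical and the variance collapses
    to the 1/tau baseline exactly.
    """
    if J < 1:
        raise ValueError("J must be at least 1")
    if tau is None:
        if model.tau is None:
            raise ValueError("model carries no tau; call compute_tau/select_length_scale first")
        tau = model.tau
    rng = np.random.default_rng(seed)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    hidden = [w.shape[1] for w in model.W[:-1]]
    if model.p_drop <= 0:
        # degenerate case: every realization is identical, so the predictive
        # variance collapses to the 1/tau baseline exactly
        pred = forward(model.W, model.b, X) * model.y_std + model.y_mean
        return UQResult(
            mean=pred, variance=np.full_like(pred, 1.0 / tau), J=J, tau=tau
        )
    n_out = model.W[-1].shape[1]
    total = np.zeros((len(X), n_out))
    total_sq = np.zeros((len(X), n_out))
    for _ in range(J):
        masks = [(rng.random((len(X), h)) >= model.p_drop).astype(float) for h in hidden]
        pred = forward(model.W, model.b, X, masks=masks)
        pred = pred * model.y_std + model.y_mean
        total += pred
        total_sq += pred**2
    mean = total / J
    second_moment = total_sq / J
    variance = 1.0 / tau + np.maximum(second_moment - mean**2, 0.0)
    return UQResult(mean=mean, variance=variance, J=J, tau=tau)


def select_length_scale(
    model: TrainedModel,
    X_train: np.ndarray,
    y_train: np.ndarray,
    grid: Sequence[float],
    J: int = 100,
    seed: int = 0,
    holdout_fraction: float = 0.2,
) -> tuple[float, list[tuple[float, float]]]:
    """Choose the GP length-scale maximizing the log predictive likelihood.

    A seeded 80/20 internal split of the training portion is used: dropout
    predictions on the held-out 20% are scored under a Gaussian with the
    MC-dropout mean and the tau(l)-dependent variance; the grid value with
    the highest summed log likelihood wins. Returns (l*, the scanned curve);
    a non-unimodal curve is a diagnostic for a too-coarse grid.
    """
    grid = [float(g) for g in grid]
    if not grid:
        raise ValueError("length-scale grid is empty")
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    y2 = np.asarray(y_train, dtype=float).reshape(len(X_train), -1)
    rng = np.random.default_rng(seed)
    n = len(X_train)
    order = rng.permutation(n)
    n_hold = max(1, int(round(holdout_fraction * n)))
    hold = order[:n_hold]
    # dropout spread does not depend on l; sample once and rescale the baseline
    base = mc_dropout_predict(model, X_train[hold], J=J, seed=seed, tau=np.inf)
    spread = base.variance  # second term of the predictive variance only
    curve: list[tuple[float, float]] = []
    for l_scale in grid:
        tau = compute_tau(model.n_train, model.lam, model.p_drop, l_scale)
        var = 1.0 / tau + spread
        resid = y2[hold] - base.mean
        ll = float(np.sum(-0.5 * np.log(2 * np.pi * var) - resid**2 / (2 * var)))
        curve.append((l_scale, ll))
    best = max(curve, key=lambda t: t[1])[0]
    return best, curve


def calibrate(
    model: TrainedModel,
    X_train: np.ndarray,
    y_train: np.ndarray,
    grid: Sequence[float],
    J: int = 100,
    seed: int = 0,
) -> TrainedModel:
    """Select l on training data and store (l, tau) on the model in place."""
    l_star, _ = select_length_scale(model, X_train, y_train, grid, J=J, seed=seed)
    model.l_scale = l_star
    model.tau = compute_tau(model.n_train, model.lam, model.p_drop, l_star)
    return model


def coverage_report(
    uq: UQResult, truths: np.ndarray
) -> tuple[float, float]:
    """Empirical fraction of truths inside the +-1 and +-2 std-dev intervals."""
    truths = np.asarray(truths, dtype=float).reshape(uq.mean.shape)
    err = np.abs(truths - uq.mean)
    one = float(np.mean(err <= uq.std))
    two = float(np.mean(err <= 2.0 * uq.std))
    return one, two
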
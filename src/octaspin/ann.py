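"""Feedforward neural network for spin-state property prediction.

Architecture and training protocol: two hidden layers of 50 tanh units and
a linear output, trained by mini-batch stochastic gradient descent on the
regularized loss

    L = (1/N) sum_n ||y_n - yhat(x_n)||^2
        + lambda * sum_l (||W_l||_F^2 + ||b_l||^2)

with dropout masks resampled per mini-batch on the hidden layers. The data
are shuffled once (seeded), the first 60% becomes the training portion and
the last 40% the test portion; lambda is chosen by 10-fold cross-validation
on the training portion, scoring the loss above on each held-out fold, and
the final network is retrained on the full training portion.

Dropout rates are target-specific: 5% for the spin-state splitting model,
15% for the exchange-sensitivity model and 30% for the bond-length model.
At inference the network runs maskless with hidden activations scaled by
the keep probability; Monte-Carlo dropout sampling for uncertainty lives in
:mod:`octaspin.uncertainty`.

Targets are z-scored internally; all reported losses and predictions are on
the original target scale unless noted. Everything is plain NumPy and fully
reproducible from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .complexes import ComplexSpec
from .descriptors import featurize_many
from .encoding import EncodingMeta, apply_encoding, fit_encoding

__all__ = [
    "TrainConfig",
    "TrainedModel",
    "TrainingDivergedError",
    "TARGET_P_DROP",
    "TARGET_UNITS",
    "init_params",
    "forward",
    "loss",
    "loss_and_grads",
    "train_network",
    "train",
    "predict",
]

#: Dropout probability per prediction target.
TARGET_P_DROP = {"splitting": 0.05, "sensitivity": 0.15, "bond": 0.30}

TARGET_UNITS = {
    "splitting": "kcal/mol",
    "sensitivity": "kcal/mol/HFX",
    "bond": "angstrom",
}

HIDDEN_WIDTH = 50
N_HIDDEN = 2


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite; lower the learning rate or raise the batch size."""


@dataclass
class TrainConfig:
    """Training protocol parameters.

    The architecture constants (2 x 50 tanh hidden layers, batch size 20,
    2000 epochs, 60/40 split, 10-fold CV over a 1e-6..1e-1 penalty grid)
    follow the reference protocol. The default learning rate of 0.1 is this
    implementation's own choice for plain SGD on z-scored targets; gradient
    clipping at norm 10 guards tanh saturation.
    """

    epochs: int = 2000
    batch_size: int = 20
    learning_rate: float = 0.1
    lambda_grid: tuple[float, ...] = (1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1)
    folds: int = 10
    split_fraction: float = 0.60
    seed: int = 0
    p_drop: float | None = None  # None -> per-target default
    cv_epochs: int | None = None  # reduced epoch count during CV; None -> epochs
    clip_norm: float = 10.0
    hidden: tuple[int, ...] = (HIDDEN_WIDTH,) * N_HIDDEN

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")
        if min(self.epochs, self.batch_size, self.folds) <= 0 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size, folds and learning_rate must be positive")


# ---------------------------------------------------------------------------
# parameters and forward/backward passes
# ---------------------------------------------------------------------------


def init_params(
    rng: np.random.Generator, n_in: int, n_out: int, hidden: Sequence[int] = (50, 50)
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Fan-in-scaled uniform initialization, biases at zero."""
    dims = [n_in, *hidden, n_out]
    W = []
    b = []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        limit = np.sqrt(6.0 / d_in)
        W.append(rng.uniform(-limit, limit, size=(d_in, d_out)))
        b.append(np.zeros(d_out))
    return W, b


def forward(
    W: list[np.ndarray],
    b: list[np.ndarray],
    X: np.ndarray,
    masks: list[np.ndarray] | None = None,
    p_drop: float = 0.0,
) -> np.ndarray:
    """Network output for encoded inputs.

    With ``masks`` (one 0/1 array per hidden layer) the masked activations
    are propagated exactly as during training. Maskless, the hidden
    activations are scaled by the keep probability ``1 - p_drop``
    (expectation-scaled inference).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != W[0].shape[0]:
        raise ValueError(f"input has {X.shape[1]} columns, network expects {W[0].shape[0]}")
    h = X
    n_hidden = len(W) - 1
    for l in range(n_hidden):
        h = np.tanh(h @ W[l] + b[l])
        if masks is not None:
            h = h * masks[l]
        elif p_drop > 0:
            h = h * (1.0 - p_drop)
    return h @ W[-1] + b[-1]


def loss(
    W: list[np.ndarray],
    b: list[np.ndarray],
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    masks: list[np.ndarray] | None = None,
    p_drop: float = 0.0,
) -> float:
    """Regularized training loss: mean squared error + L2 on weights and biases."""
    if len(np.atleast_2d(X)) == 0:
        raise ValueError("empty batch")
    pred = forward(W, b, X, masks=masks, p_drop=p_drop)
    y2 = np.atleast_2d(np.asarray(y, dtype=float).reshape(len(pred), -1))
    mse = float(np.mean(np.sum((y2 - pred) ** 2, axis=1)))
    reg = lam * (sum(float(np.sum(w**2)) for w in W) + sum(float(np.sum(v**2)) for v in b))
    out = mse + reg
    if not np.isfinite(out):
        raise TrainingDivergedError("non-finite loss; try a lower learning rate")
    return out


def loss_and_grads(
    W: list[np.ndarray],
    b: list[np.ndarray],
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    masks: list[np.ndarray] | None = None,
) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """Loss and its analytic gradients via backpropagation (training pass)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(X)
    y2 = np.asarray(y, dtype=float).reshape(n, -1)
    n_hidden = len(W) - 1
    acts = [X]  # post-mask activations feeding each layer
    pre_tanh: list[np.ndarray] = []
    h = X
    for l in range(n_hidden):
        z = h @ W[l] + b[l]
        pre_tanh.append(z)
        h = np.tanh(z)
        if masks is not None:
            h = h * masks[l]
        acts.append(h)
    pred = h @ W[-1] + b[-1]
    resid = pred - y2
    value = float(np.mean(np.sum(resid**2, axis=1)))
    value += lam * (sum(float(np.sum(w**2)) for w in W) + sum(float(np.sum(v**2)) for v in b))

    gW = [np.empty_like(w) for w in W]
    gb = [np.empty_like(v) for v in b]
    delta = 2.0 * resid / n  # d(mse)/d(pred)
    gW[-1] = acts[-1].T @ delta + 2.0 * lam * W[-1]
    gb[-1] = delta.sum(axis=0) + 2.0 * lam * b[-1]
    for l in range(n_hidden - 1, -1, -1):
        delta = delta @ W[l + 1].T
        if masks is not None:
            delta = delta * masks[l]
        delta = delta * (1.0 - np.tanh(pre_tanh[l]) ** 2)
        gW[l] = acts[l].T @ delta + 2.0 * lam * W[l]
        gb[l] = delta.sum(axis=0) + 2.0 * lam * b[l]
    return value, gW, gb


def _sample_masks(
    rng: np.random.Generator, hidden: Sequence[int], n_rows: int, p_drop: float
) -> list[np.ndarray] | None:
    if p_drop <= 0:
        return None
    return [(rng.random((n_rows, h)) >= p_drop).astype(float) for h in hidden]


def _clip(gW: list[np.ndarray], gb: list[np.ndarray], clip_norm: float) -> None:
    total = np.sqrt(sum(float(np.sum(g**2)) for g in gW + gb))
    if clip_norm > 0 and total > clip_norm:
        scale = clip_norm / total
        for g in gW:
            g *= scale
        for g in gb:
            g *= scale


def train_network(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    p_drop: float,
    config: TrainConfig,
    rng: np.random.Generator,
    epochs: int | None = None,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Mini-batch SGD on the regularized loss; returns the trained weights."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y2 = np.asarray(y, dtype=float).reshape(len(X), -1)
    W, b = init_params(rng, X.shape[1], y2.shape[1], config.hidden)
    n = len(X)
    epochs = config.epochs if epochs is None else epochs
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            masks = _sample_masks(rng, config.hidden, len(idx), p_drop)
            with np.errstate(over="ignore", invalid="ignore"):
                value, gW, gb = loss_and_grads(W, b, X[idx], y2[idx], lam, masks=masks)
            if not np.isfinite(value):
                raise TrainingDivergedError(
                    "training loss diverged; lower the learning rate"
                )
            _clip(gW, gb, config.clip_norm)
            for l in range(len(W)):
                W[l] -= config.learning_rate * gW[l]
                b[l] -= config.learning_rate * gb[l]
    return W, b


# ---------------------------------------------------------------------------
# trained-model artifact
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    """A trained network plus everything needed to reproduce its predictions."""

    W: list[np.ndarray]
    b: list[np.ndarray]
    p_drop: float
    lam: float
    learning_rate: float
    encoding_meta: EncodingMeta
    target_id: str
    y_mean: np.ndarray
    y_std: np.ndarray
    output_names: tuple[str, ...]
    training_seed: int
    n_train: int
    train_indices: np.ndarray | None = None
    test_indices: np.ndarray | None = None
    tau: float | None = None
    l_scale: float | None = None
    cv_curve: list[tuple[float, float]] | None = None
    version: str = "octaspin-model-1"

    @property
    def units(self) -> str:
        return TARGET_UNITS.get(self.target_id, "")

    def forward_encoded(
        self, X: np.ndarray, masks: list[np.ndarray] | None = None, scale_output: bool = True
    ) -> np.ndarray:
        raw = forward(self.W, self.b, X, masks=masks, p_drop=self.p_drop if masks is None else 0.0)
        if scale_output:
            raw = raw * self.y_std + self.y_mean
        return raw

    def predict_specs(self, specs: Sequence[ComplexSpec]) -> np.ndarray:
        include_a_hf = self.target_id != "sensitivity"
        vectors = featurize_many(specs, set_id=self.encoding_meta.set_id, include_a_hf=include_a_hf)
        X = apply_encoding(vectors, self.encoding_meta)
        return self.forward_encoded(X)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "target_id": self.target_id,
            "p_drop": self.p_drop,
            "lambda": self.lam,
            "learning_rate": self.learning_rate,
            "training_seed": self.training_seed,
            "n_train": self.n_train,
            "tau": self.tau,
            "l_scale": self.l_scale,
            "y_mean": self.y_mean.tolist(),
            "y_std": self.y_std.tolist(),
            "output_names": list(self.output_names),
            "encoding_meta": self.encoding_meta.to_dict(),
            "weights": [w.tolist() for w in self.W],
            "biases": [v.tolist() for v in self.b],
        }

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedModel":
        return cls(
            W=[np.asarray(w, dtype=float) for w in d["weights"]],
            b=[np.asarray(v, dtype=float) for v in d["biases"]],
            p_drop=float(d["p_drop"]),
            lam=float(d["lambda"]),
            learning_rate=float(d["learning_rate"]),
            encoding_meta=EncodingMeta.from_dict(d["encoding_meta"]),
            target_id=d["target_id"],
            y_mean=np.asarray(d["y_mean"], dtype=float),
            y_std=np.asarray(d["y_std"], dtype=float),
            output_names=tuple(d["output_names"]),
            training_seed=int(d["training_seed"]),
            n_train=int(d["n_train"]),
            tau=d.get("tau"),
            l_scale=d.get("l_scale"),
            version=d.get("version", "octaspin-model-1"),
        )

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# training protocol
# ---------------------------------------------------------------------------


def _cv_select_lambda_ann(
    X: np.ndarray,
    y: np.ndarray,
    p_drop: float,
    config: TrainConfig,
    rng: np.random.Generator,
) -> tuple[float, list[tuple[float, float]]]:
    """10-fold CV over the penalty grid, scoring the regularized loss on held-out folds."""
    n = len(X)
    folds = min(config.folds, n)
    order = rng.permutation(n)
    fold_ids = np.array_split(order, folds)
    curve: list[tuple[float, float]] = []
    epochs = config.cv_epochs or config.epochs
    for lam in sorted(config.lambda_grid):
        errs = []
        for k in range(folds):
            test_idx = fold_ids[k]
            train_idx = np.concatenate([fold_ids[j] for j in range(folds) if j != k])
            sub_rng = np.random.default_rng(rng.integers(2**31))
            W, b = train_network(X[train_idx], y[train_idx], lam, p_drop, config, sub_rng, epochs=epochs)
            errs.append(loss(W, b, X[test_idx], y[test_idx], lam, p_drop=p_drop))
        curve.append((float(lam), float(np.mean(errs))))
    best = min(curve, key=lambda t: t[1])[0]
    return best, curve


def train(
    specs: Sequence[ComplexSpec],
    y: np.ndarray,
    target_id: str,
    config: TrainConfig | None = None,
    set_id: str = "g",
    output_names: Sequence[str] | None = None,
) -> TrainedModel:
    """Run the full training protocol on featurizable complexes.

    Shuffle (seeded), 60/40 train/test split, cross-validated penalty
    selection on the training portion (skipped when the grid has a single
    value), then retraining on the full training portion. Targets may be a
    vector or an ``(n, 2)`` array for the joint low-/high-spin bond-length
    model.
    """
    config = config or TrainConfig()
    if target_id not in TARGET_P_DROP:
        raise ValueError(f"target_id must be one of {sorted(TARGET_P_DROP)}")
    p_drop = config.p_drop if config.p_drop is not None else TARGET_P_DROP[target_id]
    y2 = np.asarray(y, dtype=float).reshape(len(specs), -1)
    if output_names is None:
        output_names = [target_id] if y2.shape[1] == 1 else [f"{target_id}_{i}" for i in range(y2.shape[1])]

    include_a_hf = target_id != "sensitivity"
    vectors = featurize_many(specs, set_id=set_id, include_a_hf=include_a_hf)

    rng = np.random.default_rng(config.seed)
    n = len(vectors)
    order = rng.permutation(n)
    n_train = max(1, int(round(config.split_fraction * n)))
    train_idx, test_idx = order[:n_train], order[n_train:]

    meta = fit_encoding([vectors[i] for i in train_idx], mode="ann")
    X = apply_encoding(vectors, meta)
    y_mean = y2[train_idx].mean(axis=0)
    y_std = y2[train_idx].std(axis=0, ddof=0)
    y_std[y_std == 0] = 1.0
    ys = (y2 - y_mean) / y_std

    if len(config.lambda_grid) > 1 and len(train_idx) >= config.folds:
        lam, curve = _cv_select_lambda_ann(X[train_idx], ys[train_idx], p_drop, config, rng)
    else:
        lam, curve = float(config.lambda_grid[0]), None

    W, b = train_network(X[train_idx], ys[train_idx], lam, p_drop, config, rng)
    return TrainedModel(
        W=W,
        b=b,
        p_drop=p_drop,
        lam=lam,
        learning_rate=config.learning_rate,
        encoding_meta=meta,
        target_id=target_id,
        y_mean=y_mean,
        y_std=y_std,
        output_names=tuple(output_names),
        training_seed=config.seed,
        n_train=len(train_idx),
        train_indices=train_idx,
        test_indices=test_idx,
        cv_curve=curve,
    )


def predict(model: TrainedModel, specs: Sequence[ComplexSpec]) -> np.ndarray:
    """Inference-mode predictions in target units (kcal/mol, kcal/mol/HFX or angstrom)."""
    return model.predict_specs(specs)
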
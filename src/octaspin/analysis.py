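"""Downstream science on top of the trained models.

Sign convention used throughout: the spin-state splitting is
DeltaE_H-L = E(high spin) - E(low spin), so negative values favor the
high-spin ground state and increasing Hartree-Fock exchange (which
stabilizes high-spin states) drives the splitting down — exchange
sensitivities are negative, from roughly -13 kcal/mol/HFX for weak-field
Cr(iii) amines to -174 kcal/mol/HFX for strong-field hexacarbonyls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.kernel_ridge import KernelRidge
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeClassifier

from .lasso import rmse

__all__ = [
    "classify_ground_state",
    "fit_sensitivity",
    "SensitivityFit",
    "extrapolate_delta_ml",
    "descriptor_distance",
    "DistanceReport",
    "build_classification_tree",
    "ClassificationTree",
    "baseline_fit",
    "BaselineResult",
]

#: Half-width (kcal/mol) of the near-degenerate band around zero splitting.
DEGENERACY_BAND = 5.0


def classify_ground_state(delta_e: float, degeneracy_band: float = DEGENERACY_BAND) -> str:
    """Label a splitting as ``"high"``, ``"low"`` or ``"near-degenerate"``.

    Negative DeltaE_H-L means the high-spin state lies below the low-spin
    state; splittings within the +-band are flagged near-degenerate
    (spin-crossover candidates).
    """
    if not np.isfinite(delta_e):
        raise ValueError("splitting must be finite")
    if abs(delta_e) < degeneracy_band:
        return "near-degenerate"
    return "high" if delta_e < 0 else "low"


@dataclass(frozen=True)
class SensitivityFit:
    slope: float  # kcal/mol/HFX (1 HFX = 0 -> 100% exchange)
    intercept: float  # kcal/mol at a_HF = 0
    r_squared: float
    stderr: float  # standard error of the slope
    n_points: int


def fit_sensitivity(a_hf: Sequence[float], delta_e: Sequence[float]) -> SensitivityFit:
    """Least-squares slope of DeltaE_H-L against the exchange fraction.

    ``a_hf`` is the exchange fraction (0.00-0.30), so the returned slope is
    already in kcal/mol/HFX: one HFX unit spans 0 to 100% exchange.
    """
    a = np.asarray(a_hf, dtype=float)
    e = np.asarray(delta_e, dtype=float)
    if a.shape != e.shape or a.ndim != 1:
        raise ValueError("a_hf and delta_e must be 1-D and aligned")
    if len(np.unique(a)) < 2:
        raise ValueError("at least two distinct exchange fractions are required")
    res = stats.linregress(a, e)
    return SensitivityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        stderr=float(res.stderr) if np.isfinite(res.stderr) else 0.0,
        n_points=len(a),
    )


def extrapolate_delta_ml(
    e_at_x0: float | np.ndarray, slope: float | np.ndarray, x0: float, x1: float
) -> float | np.ndarray:
    """Linear exchange extrapolation E(x1) = E(x0) + slope * (x1 - x0).

    The delta-learning use case: correct a cheap semi-local (a_HF = 0)
    splitting with a learned exchange sensitivity to estimate the hybrid
    result at a_HF = x1.
    """
    return e_at_x0 + slope * (x1 - x0)


@dataclass
class DistanceReport:
    """Nearest-training-point distances per query in normalized descriptor space."""

    euclidean: np.ndarray
    uncentered_pearson: np.ndarray
    nearest_index: np.ndarray
    flagged: np.ndarray  # True where the Euclidean distance exceeds the threshold
    threshold: float


def descriptor_distance(
    X_query: np.ndarray,
    X_train: np.ndarray,
    threshold: float = 1.0,
) -> DistanceReport:
    """Distance of each query to its closest training descriptor vector.

    Both matrices must share the same encoding meta (same columns, same
    normalization). The Euclidean nearest-neighbour distance above the
    threshold (default 1.0) flags predictions as unreliable: large errors
    concentrate beyond that radius. The uncentered Pearson distance
    1 - x.t / (||x|| ||t||) is reported alongside as a shape-only metric.
    """
    Q = np.atleast_2d(np.asarray(X_query, dtype=float))
    T = np.atleast_2d(np.asarray(X_train, dtype=float))
    if Q.shape[1] != T.shape[1]:
        raise ValueError(
            f"query has {Q.shape[1]} columns but training matrix has {T.shape[1]}; "
            "encode both with the same encoding meta"
        )
    dists = cdist(Q, T, metric="euclidean")
    nearest = np.argmin(dists, axis=1)
    eucl = dists[np.arange(len(Q)), nearest]

    qn = np.linalg.norm(Q, axis=1)
    tn = np.linalg.norm(T, axis=1)
    denom = np.outer(qn, tn)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(denom > 0, (Q @ T.T) / denom, 0.0)
    pearson_d = 1.0 - np.max(cos, axis=1)
    return DistanceReport(
        euclidean=eucl,
        uncentered_pearson=pearson_d,
        nearest_index=nearest,
        flagged=eucl > threshold,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# recursive binary classification tree ("spectrochemical tree")
# ---------------------------------------------------------------------------


@dataclass
class TreeLeaf:
    rule: str
    n: int
    population_share: float
    majority: str
    purity: float


@dataclass
class ClassificationTree:
    """Pruned binary tree over descriptors predicting high- vs low-spin."""

    estimator: DecisionTreeClassifier
    feature_names: list[str]
    classes: list[str]
    leaves: list[TreeLeaf]
    ccp_alpha: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(X)

    def to_text(self) -> str:
        from sklearn.tree import export_text

        return export_text(self.estimator, feature_names=self.feature_names)

    def to_dot(self) -> str:
        from io import StringIO

        from sklearn.tree import export_graphviz

        buf = StringIO()
        export_graphviz(
            self.estimator,
            out_file=buf,
            feature_names=self.feature_names,
            class_names=self.classes,
            filled=False,
            impurity=True,
        )
        return buf.getvalue()


def _leaf_rules(tree: DecisionTreeClassifier, feature_names: list[str]) -> dict[int, str]:
    t = tree.tree_
    rules: dict[int, str] = {}

    def walk(node: int, path: list[str]) -> None:
        if t.children_left[node] == -1:
            rules[node] = " and ".join(path) if path else "(root)"
            return
        name = feature_names[t.feature[node]]
        thr = t.threshold[node]
        walk(t.children_left[node], path + [f"{name} <= {thr:.3g}"])
        walk(t.children_right[node], path + [f"{name} > {thr:.3g}"])

    walk(0, [])
    return rules


def build_classification_tree(
    X: np.ndarray,
    labels: Sequence[str],
    feature_names: Sequence[str],
    max_splits: int = 6,
    min_leaf: int = 10,
    prune_folds: int = 10,
    seed: int = 0,
) -> ClassificationTree:
    """Greedy impurity-minimizing binary tree with cost-complexity pruning.

    At most ``max_splits`` divisions (so at most ``max_splits + 1`` leaves),
    each leaf holding at least ``min_leaf`` points. Pruning removes
    statistically weak branches by the cost-complexity path with a 1-SE
    rule on cross-validated accuracy. Leaves report their majority class,
    purity and share of the total population.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(labels)
    if len(X) == 0:
        raise ValueError("empty dataset")
    base = DecisionTreeClassifier(
        criterion="gini",
        max_leaf_nodes=max_splits + 1,
        min_samples_leaf=min_leaf,
        random_state=seed,
    )
    base.fit(X, y)
    # cost-complexity pruning with a 1-SE rule
    path = base.cost_complexity_pruning_path(X, y)
    alphas = np.unique(path.ccp_alphas)
    best_alpha = 0.0
    if len(alphas) > 1 and len(X) >= prune_folds:
        cv = KFold(n_splits=prune_folds, shuffle=True, random_state=seed)
        scores = []
        for alpha in alphas:
            accs = []
            for tr, te in cv.split(X):
                clf = DecisionTreeClassifier(
                    criterion="gini",
                    max_leaf_nodes=max_splits + 1,
                    min_samples_leaf=min_leaf,
                    random_state=seed,
                    ccp_alpha=float(alpha),
                )
                clf.fit(X[tr], y[tr])
                accs.append(clf.score(X[te], y[te]))
            scores.append((float(alpha), float(np.mean(accs)), float(np.std(accs) / np.sqrt(len(accs)))))
        best_mean = max(s[1] for s in scores)
        se_at_best = next(s[2] for s in scores if s[1] == best_mean)
        # largest alpha whose CV accuracy is within one SE of the best
        eligible = [s[0] for s in scores if s[1] >= best_mean - se_at_best]
        best_alpha = max(eligible)
    tree = DecisionTreeClassifier(
        criterion="gini",
        max_leaf_nodes=max_splits + 1,
        min_samples_leaf=min_leaf,
        random_state=seed,
        ccp_alpha=best_alpha,
    )
    tree.fit(X, y)

    rules = _leaf_rules(tree, list(feature_names))
    leaf_ids = tree.apply(X)
    classes = list(tree.classes_)
    leaves = []
    for node, rule in rules.items():
        members = leaf_ids == node
        n = int(members.sum())
        counts = tree.tree_.value[node][0]
        maj = classes[int(np.argmax(counts))]
        purity = float(np.max(counts) / np.sum(counts))
        leaves.append(
            TreeLeaf(
                rule=rule,
                n=n,
                population_share=n / len(X),
                majority=maj,
                purity=purity,
            )
        )
    return ClassificationTree(
        estimator=tree,
        feature_names=list(feature_names),
        classes=classes,
        leaves=leaves,
        ccp_alpha=float(best_alpha),
    )


# ---------------------------------------------------------------------------
# KRR / SVR baselines
# ---------------------------------------------------------------------------


@dataclass
class BaselineResult:
    method: str
    model: object
    best_params: dict
    train_rmse: float
    test_rmse: float
    train_max_ue: float
    test_max_ue: float
    train_indices: np.ndarray
    test_indices: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X)


def baseline_fit(
    X: np.ndarray,
    y: np.ndarray,
    method: str = "krr",
    gamma_grid: Sequence[float] = (1e-3, 1e-2, 1e-1, 1.0),
    reg_grid: Sequence[float] = (1e-4, 1e-3, 1e-2, 1e-1, 1.0),
    epsilon_grid: Sequence[float] = (0.01, 0.1, 0.5),
    folds: int = 10,
    seed: int = 0,
    split_fraction: float = 0.60,
) -> BaselineResult:
    """Grid-searched square-exponential-kernel baseline on a 60/40 split.

    ``krr`` fits kernel ridge regression (closed-form (K + lambda I)^-1 y),
    ``svr`` an epsilon-insensitive support vector regression; both use the
    RBF (square-exponential) kernel and 10-fold cross-validated grid search
    over kernel width and regularization, with the same shuffled 60/40
    split convention as the network for comparability.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(X))
    n_train = max(1, int(round(split_fraction * len(X))))
    tr, te = order[:n_train], order[n_train:]

    cv = KFold(n_splits=min(folds, len(tr)), shuffle=True, random_state=seed)
    if method == "krr":
        grid = {"alpha": list(reg_grid), "gamma": list(gamma_grid)}
        search = GridSearchCV(KernelRidge(kernel="rbf"), grid, cv=cv, scoring="neg_mean_squared_error")
    elif method == "svr":
        grid = {
            "C": [1.0 / r for r in reg_grid],
            "gamma": list(gamma_grid),
            "epsilon": list(epsilon_grid),
        }
        search = GridSearchCV(SVR(kernel="rbf"), grid, cv=cv, scoring="neg_mean_squared_error")
    else:
        raise ValueError("method must be 'krr' or 'svr'")
    search.fit(X[tr], y[tr])
    model = search.best_estimator_
    pred_tr = model.predict(X[tr])
    pred_te = model.predict(X[te]) if len(te) else np.array([])
    return BaselineResult(
        method=method,
        model=model,
        best_params=search.best_params_,
        train_rmse=rmse(y[tr], pred_tr),
        test_rmse=rmse(y[te], pred_te) if len(te) else float("nan"),
        train_max_ue=float(np.max(np.abs(y[tr] - pred_tr))),
        test_max_ue=float(np.max(np.abs(y[te] - pred_te))) if len(te) else float("nan"),
        train_indices=tr,
        test_indices=te,
    )
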
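"""Classifiers: soft-margin RBF-SVM with grid search, Fisher LDA, BP-ANN.

The SVM solves the usual soft-margin problem

    min_{w,b,xi}  1/2 <w, w> + C sum_i xi_i
    s.t.          y_i (<w, x_i> + b) >= 1 - xi_i,   xi_i >= 0

in its dual form with an RBF kernel ``K(x_i, x_j) = exp(-gamma ||x_i - x_j||^2)``;
``C`` and ``gamma`` are chosen by stratified cross-validated grid search.
The LDA is the classic Fisher discriminant (pooled within-class covariance,
midpoint threshold).  The ANN is a one-hidden-layer feed-forward network
with ten tanh hidden units and a linear output trained on +-1 targets.

``loocv_evaluate`` runs the *entire* training procedure — normalization
fit, hyperparameter search, final fit — inside each leave-one-out fold, so
the held-out unit never influences any fitted quantity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVC

from .dataset import FeatureMatrix, NormalizationParams, apply_min_max, fit_min_max

__all__ = [
    "SVMConfig",
    "TrainedClassifier",
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
    "train_svm",
    "train_lda",
    "train_ann",
    "predict",
    "loocv_evaluate",
]

#: libsvm-style log-spaced grids (multiplicative steps of 4).
DEFAULT_C_GRID = tuple(float(2.0 ** e) for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(float(2.0 ** e) for e in range(-15, 4, 2))


@dataclass
class SVMConfig:
    grid_c: Sequence[float] = DEFAULT_C_GRID
    grid_gamma: Sequence[float] = DEFAULT_GAMMA_GRID
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if not self.grid_c or not self.grid_gamma:
            raise ValueError("hyperparameter grids must be non-empty")
        if min(self.grid_c) <= 0 or min(self.grid_gamma) <= 0:
            raise ValueError("C and gamma candidates must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class TrainedClassifier:
    """A fitted model with a signed decision score (higher = more nodule-like)."""

    kind: str
    model: object
    hyperparams: dict
    score_fn: Callable[[np.ndarray], np.ndarray]
    n_features: int
    grid_table: list[dict] = field(default_factory=list)


def _check_training_matrix(matrix: FeatureMatrix) -> None:
    if len(set(matrix.labels)) < 2:
        raise ValueError("both classes must be present for training")
    if not np.all(np.isfinite(matrix.values)):
        raise ValueError("feature matrix contains non-finite values")


def grid_search_svm(x: np.ndarray, y: np.ndarray, config: SVMConfig,
                    seed: int = 0) -> tuple[float, float, list[dict]]:
    """Pick (C, gamma) by stratified k-fold CV accuracy.

    Ties are broken toward smaller C, then smaller gamma (grids are scanned
    in ascending order and only strict improvements replace the incumbent).
    """
    n_splits = min(config.cv_folds, int(np.bincount((y > 0).astype(int)).min()))
    n_splits = max(n_splits, 2)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = list(skf.split(x, y))
    table: list[dict] = []
    best_acc = -1.0
    best = (None, None)
    for c in sorted(config.grid_c):
        for g in sorted(config.grid_gamma):
            correct = 0
            for tr, te in folds:
                clf = SVC(C=c, gamma=g, kernel="rbf")
                clf.fit(x[tr], y[tr])
                correct += int((clf.predict(x[te]) == y[te]).sum())
            acc = correct / len(y)
            table.append({"C": c, "gamma": g, "cv_accuracy": acc})
            if acc > best_acc:
                best_acc = acc
                best = (c, g)
    return best[0], best[1], table


def train_svm(matrix: FeatureMatrix, config: SVMConfig | None = None,
              seed: int = 0) -> TrainedClassifier:
    """Grid-searched soft-margin RBF-SVM, refit on all input data."""
    _check_training_matrix(matrix)
    config = config or SVMConfig()
    x, y = matrix.values, matrix.labels
    c, g, table = grid_search_svm(x, y, config, seed=seed)
    clf = SVC(C=c, gamma=g, kernel="rbf")
    clf.fit(x, y)
    return TrainedClassifier(
        kind="svm", model=clf, hyperparams={"C": c, "gamma": g},
        score_fn=clf.decision_function, n_features=x.shape[1], grid_table=table,
    )


def train_lda(matrix: FeatureMatrix, ridge_eps: float = 1e-6) -> TrainedClassifier:
    """Fisher linear discriminant with pooled within-class covariance.

    Direction ``w = Sw^{-1} (mu+ - mu-)``; threshold at the midpoint of the
    projected class means.  A ridge ``eps * trace(Sw)/d * I`` is added when
    the pooled covariance is singular or ill-conditioned.
    """
    _check_training_matrix(matrix)
    x, y = matrix.values, matrix.labels
    xp, xn = x[y == 1], x[y == -1]
    mu_p, mu_n = xp.mean(axis=0), xn.mean(axis=0)
    d = x.shape[1]
    sw = np.zeros((d, d))
    for part, mu in ((xp, mu_p), (xn, mu_n)):
        dev = part - mu
        sw += dev.T @ dev
    sw /= max(len(y) - 2, 1)
    applied_eps = 0.0
    try:
        if np.linalg.cond(sw) > 1e12:
            raise np.linalg.LinAlgError("ill-conditioned")
        w = np.linalg.solve(sw, mu_p - mu_n)
    except np.linalg.LinAlgError:
        applied_eps = ridge_eps * (np.trace(sw) / d if np.trace(sw) > 0 else 1.0)
        w = np.linalg.solve(sw + applied_eps * np.eye(d), mu_p - mu_n)
    b = -0.5 * float(w @ (mu_p + mu_n))

    def score_fn(xq: np.ndarray) -> np.ndarray:
        return np.asarray(xq, dtype=float) @ w + b

    return TrainedClassifier(
        kind="lda", model={"w": w, "b": b, "ridge_eps": applied_eps},
        hyperparams={"ridge_eps": applied_eps},
        score_fn=score_fn, n_features=d,
    )


def train_ann(matrix: FeatureMatrix, seed: int = 0, hidden: int = 10,
              max_iter: int = 1000) -> TrainedClassifier:
    """One-hidden-layer network: ``hidden`` tanh units -> linear output.

    Trained as a regression onto +-1 targets (linear output layer) with a
    seeded initialization, so the fitted weights are reproducible for a
    given seed.  Non-convergence within the iteration cap yields a warning
    and the best model found so far.
    """
    _check_training_matrix(matrix)
    x, y = matrix.values, matrix.labels.astype(float)
    net = MLPRegressor(hidden_layer_sizes=(hidden,), activation="tanh",
                       solver="lbfgs", max_iter=max_iter, random_state=seed)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        net.fit(x, y)
    if getattr(net, "n_iter_", 0) >= max_iter:
        warnings.warn("ANN did not converge within the iteration cap; "
                      "using best-so-far weights", stacklevel=2)
    return TrainedClassifier(
        kind="ann", model=net, hyperparams={"hidden": hidden, "seed": seed},
        score_fn=lambda xq: np.asarray(net.predict(xq), dtype=float),
        n_features=x.shape[1],
    )


def predict(model: TrainedClassifier, matrix: FeatureMatrix | np.ndarray,
            ) -> tuple[np.ndarray, np.ndarray]:
    """Labels (+1/-1) and real-valued scores; score 0 maps to the negative class."""
    x = matrix.values if isinstance(matrix, FeatureMatrix) else np.asarray(matrix, float)
    if x.size == 0:
        return np.array([], dtype=int), np.array([])
    if x.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} features, got {x.shape[1]}")
    scores = np.asarray(model.score_fn(x), dtype=float)
    labels = np.where(scores > 0, 1, -1)
    return labels, scores


TRAINERS = {
    "svm": lambda m, seed, **kw: train_svm(m, kw.get("svm_config"), seed=seed),
    "lda": lambda m, seed, **kw: train_lda(m),
    "ann": lambda m, seed, **kw: train_ann(m, seed=seed),
}


def loocv_evaluate(matrix: FeatureMatrix, classifier: str = "svm",
                   grouping: str = "image", seed: int = 0,
                   svm_config: SVMConfig | None = None,
                   normalize: bool = True,
                   grid_mode: str = "nested",
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Leave-one-out evaluation with per-fold refitting of everything.

    ``grouping="image"`` holds out one sample at a time; ``"patient"`` holds
    out all samples of one patient together (images of one patient are
    correlated, so image-level LOOCV is the optimistic variant).
    ``grid_mode="nested"`` reruns the SVM grid search inside every fold;
    ``"global"`` runs it once on the full matrix and reuses the chosen
    (C, gamma) in each fold — cheaper and mildly optimistic.

    Returns (true labels, predicted labels, scores) in input order.
    """
    if classifier not in TRAINERS:
        raise ValueError(f"unknown classifier {classifier!r}")
    if grouping not in ("image", "patient"):
        raise ValueError(f"unknown grouping {grouping!r}")
    if grid_mode not in ("nested", "global"):
        raise ValueError(f"unknown grid_mode {grid_mode!r}")
    n = matrix.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples for LOOCV")
    if grouping == "patient":
        if not matrix.patient_ids:
            raise ValueError("grouping='patient' requires patient_ids")
        units = [np.flatnonzero(np.array(matrix.patient_ids) == pid)
                 for pid in dict.fromkeys(matrix.patient_ids)]
    else:
        units = [np.array([i]) for i in range(n)]

    fixed_config = svm_config or SVMConfig()
    if classifier == "svm" and grid_mode == "global":
        work = matrix
        if normalize:
            work = apply_min_max(matrix, fit_min_max(matrix))
        c, g, _ = grid_search_svm(work.values, work.labels, fixed_config, seed=seed)
        fixed_config = SVMConfig(grid_c=[c], grid_gamma=[g],
                                 cv_folds=fixed_config.cv_folds)

    y_true = matrix.labels.copy()
    y_pred = np.zeros(n, dtype=int)
    scores = np.zeros(n, dtype=float)
    for unit in units:
        train_idx = np.setdiff1d(np.arange(n), unit)
        train_m = matrix.subset_rows(train_idx)
        test_values = matrix.values[unit]
        if normalize:
            params = fit_min_max(train_m)
            train_m = apply_min_max(train_m, params)
            span = np.where(params.maxs == params.mins, 1.0, params.maxs - params.mins)
            test_values = np.clip((test_values - params.mins) / span, 0.0, 1.0)
            test_values[:, params.degenerate] = 0.0
        model = TRAINERS[classifier](train_m, seed, svm_config=fixed_config)
        labels, sc = predict(model, test_values)
        y_pred[unit] = labels
        scores[unit] = sc
    return y_true, y_pred, scores
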
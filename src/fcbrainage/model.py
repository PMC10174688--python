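"""Linear support-vector age regression with permutation significance.

The model is an epsilon-insensitive support-vector regression with a linear
kernel and the scikit-learn default hyperparameters (C = 1.0, epsilon =
0.1), trained on Fisher-z edge features.  Accuracy is the Pearson
correlation between observed and predicted age plus the mean absolute
error (years); significance comes from a label-shuffling permutation test
that refits the entire cross-validation each time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold
from sklearn.svm import SVR

__all__ = [
    "BrainAgeModel",
    "PredictionReport",
    "fit_brainage",
    "predict_age",
    "crossval_predict",
    "accuracy",
    "mae",
    "permutation_pvalue",
    "prediction_report",
]


@dataclass(frozen=True)
class BrainAgeModel:
    """Portable linear age model: weights (years per z-unit) + intercept.

    ``edge_index`` records the canonical edge ordering the model was
    trained on so that prediction can refuse mismatched feature spaces.
    """

    weights: np.ndarray
    intercept: float
    c_param: float = 1.0
    epsilon: float = 0.1
    edge_index: tuple[tuple[int, int], ...] = ()
    n_train: int = 0
    age_range: tuple[float, float] = (float("nan"), float("nan"))
    seed: int | None = None
    standardize: bool = False
    feature_mean: np.ndarray | None = None
    feature_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float).ravel()
        if self.edge_index and len(w) != len(self.edge_index):
            raise ValueError("weights length must match edge_index length")
        if self.c_param <= 0:
            raise ValueError("c_param must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")
        object.__setattr__(self, "weights", w)

    @property
    def n_features(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class PredictionReport:
    predicted: np.ndarray
    observed: np.ndarray
    r: float
    mae: float
    p_r: float | None = None
    p_mae: float | None = None
    k_folds: int = 5
    seed: int | None = None


def _validate_xy(features, ages):
    X = np.asarray(features, dtype=float)
    y = np.asarray(ages, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("features must be a 2-D subjects x edges array")
    if X.shape[0] != len(y):
        raise ValueError("features and ages disagree on subject count")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    if not np.all(np.isfinite(y)):
        raise ValueError("ages contain non-finite values")
    return X, y


def fit_brainage(
    features,
    ages,
    c_param: float = 1.0,
    epsilon: float = 0.1,
    standardize: bool = False,
    edge_index: tuple[tuple[int, int], ...] = (),
    seed: int | None = None,
    tol: float = 1e-6,
) -> BrainAgeModel:
    """Fit the linear epsilon-SVR.  No feature standardization by default
    (matching a plain default-parameter fit); set ``standardize=True`` to
    z-score features on the training set.  ``tol`` is the solver
    convergence tolerance, tightened beyond the library default so the
    fitted weights are numerically stable at the problem sizes used here.
    """
    X, y = _validate_xy(features, ages)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 training subjects")
    if np.unique(y).size < 2:
        # degenerate but well defined: predict the constant age
        return BrainAgeModel(
            weights=np.zeros(X.shape[1]),
            intercept=float(y[0]),
            c_param=c_param,
            epsilon=epsilon,
            edge_index=tuple(edge_index),
            n_train=len(y),
            age_range=(float(y.min()), float(y.max())),
            seed=seed,
            standardize=standardize,
        )
    mu = sd = None
    Xf = X
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        Xf = (X - mu) / sd
    svr = SVR(kernel="linear", C=c_param, epsilon=epsilon, tol=tol)
    svr.fit(Xf, y)
    return BrainAgeModel(
        weights=svr.coef_.ravel().copy(),
        intercept=float(svr.intercept_[0]),
        c_param=c_param,
        epsilon=epsilon,
        edge_index=tuple(edge_index),
        n_train=len(y),
        age_range=(float(y.min()), float(y.max())),
        seed=seed,
        standardize=standardize,
        feature_mean=mu,
        feature_sd=sd,
    )


def predict_age(model: BrainAgeModel, features) -> np.ndarray:
    """Apply the linear model: weights . features + intercept."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match the model's "
            f"edge space ({model.n_features} edges); check that features "
            "were built with the same parcellation and edge ordering"
        )
    if model.standardize and model.feature_mean is not None:
        X = (X - model.feature_mean) / model.feature_sd
    return X @ model.weights + model.intercept


def crossval_predict(
    features,
    ages,
    k: int = 5,
    seed: int | None = 0,
    **fit_kwargs,
) -> np.ndarray:
    """Out-of-fold predictions from a seeded shuffled k-fold partition.

    Every subject is predicted exactly once, by a model never trained on
    it; with k = n this is leave-one-out.
    """
    X, y = _validate_xy(features, ages)
    n = len(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k = {k} exceeds the number of subjects ({n})")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    pred = np.empty(n)
    for train_idx, test_idx in kf.split(X):
        m = fit_brainage(X[train_idx], y[train_idx], **fit_kwargs)
        pred[test_idx] = predict_age(m, X[test_idx])
    return pred


def mae(predicted, observed) -> float:
    """Mean absolute error in years."""
    p = np.asarray(predicted, dtype=float).ravel()
    o = np.asarray(observed, dtype=float).ravel()
    if len(p) != len(o):
        raise ValueError("predicted and observed lengths differ")
    return float(np.mean(np.abs(p - o)))


def accuracy(predicted, observed) -> dict[str, float]:
    """Pearson r between observed and predicted age, plus MAE (years)."""
    p = np.asarray(predicted, dtype=float).ravel()
    o = np.asarray(observed, dtype=float).ravel()
    if len(p) != len(o):
        raise ValueError("predicted and observed lengths differ")
    if len(p) < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(o) == 0:
        raise ValueError(
            "observed ages are constant; r is undefined (use mae())"
        )
    r = float(stats.pearsonr(p, o).statistic)
    return {"r": r, "mae": mae(p, o)}


def permutation_pvalue(
    features,
    ages,
    n_perm: int = 1000,
    seed: int | None = 0,
    metric: str = "r",
    k: int = 5,
    **fit_kwargs,
) -> float:
    """Label-shuffling permutation p-value for the cross-validated metric.

    Ages are permuted ``n_perm`` times and the full cross-validation is
    refit each time (preserving exchangeability).  "At least as extreme"
    means >= the observed r, or <= the observed MAE.  The add-one
    convention p = (1 + hits) / (1 + n_perm) keeps p strictly positive.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if metric not in ("r", "mae"):
        raise ValueError("metric must be 'r' or 'mae'")
    X, y = _validate_xy(features, ages)
    rng = np.random.default_rng(seed)

    def cv_metric(labels):
        pred = crossval_predict(X, labels, k=k, seed=seed, **fit_kwargs)
        if metric == "r":
            return accuracy(pred, labels)["r"]
        return mae(pred, labels)

    observed = cv_metric(y)
    hits = 0
    for _ in range(n_perm):
        perm = cv_metric(rng.permutation(y))
        if metric == "r":
            hits += perm >= observed
        else:
            hits += perm <= observed
    return (1 + hits) / (1 + n_perm)


def prediction_report(
    features,
    ages,
    k: int = 5,
    seed: int | None = 0,
    n_perm: int | None = None,
    **fit_kwargs,
) -> PredictionReport:
    """Cross-validated accuracy summary, optionally with permutation p's."""
    X, y = _validate_xy(features, ages)
    pred = crossval_predict(X, y, k=k, seed=seed, **fit_kwargs)
    acc = accuracy(pred, y)
    p_r = p_mae = None
    if n_perm:
        p_r = permutation_pvalue(
            X, y, n_perm=n_perm, seed=seed, metric="r", k=k, **fit_kwargs
        )
        p_mae = permutation_pvalue(
            X, y, n_perm=n_perm, seed=seed, metric="mae", k=k, **fit_kwargs
        )
    return PredictionReport(
        predicted=pred, observed=y, r=acc["r"], mae=acc["mae"],
        p_r=p_r, p_mae=p_mae, k_folds=k, seed=seed,
    )
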
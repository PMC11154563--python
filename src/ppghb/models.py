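"""Hemoglobin regression: model families, grid search, CV, metrics, agreement.

Three families are supported — AdaBoost regression on decision trees, a
two-hidden-layer feed-forward network (BPNN) and random-forest regression —
each with the hyperparameter grid used in the study protocol: tree ensembles
search 1–10 estimators × depth 1–6; the network searches activation
{identity, logistic, tanh, relu} × solver {lbfgs, sgd, adam} at 10 000 max
iterations.  Protocol: a seeded 7:3 train/test split, exhaustive grid search
scored by mean 10-fold cross-validated R² on the training set (ties broken
toward the smaller model), a final refit on the full training set, and
R²/MSE/MAE plus Bland–Altman 95% limits of agreement on the held-out test set.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.compose import TransformedTargetRegressor
from sklearn.ensemble import AdaBoostRegressor, RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "Dataset",
    "GridSpec",
    "CVCandidate",
    "GridSearchResult",
    "RegressionReport",
    "split_7_3",
    "grid_search_cv",
    "fit_predict",
    "regression_metrics",
    "bland_altman",
    "pearson_matrix",
    "evaluate_family",
]

FAMILIES = ("adaboost", "bpnn", "random_forest")


@dataclass(frozen=True)
class Dataset:
    """Feature matrix (8 or 9 columns) and hemoglobin targets in g/L."""

    X: np.ndarray
    y: np.ndarray
    feature_names: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "X", np.atleast_2d(np.asarray(self.X, dtype=float)))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise ValueError("dataset must not contain missing values")

    @property
    def n(self) -> int:
        return self.y.size

    def subset(self, idx: np.ndarray) -> "Dataset":
        return Dataset(self.X[idx], self.y[idx], self.feature_names)


def split_7_3(ds: Dataset, seed: int = 0) -> tuple[Dataset, Dataset]:
    """Seeded random 7:3 split; the test set gets round(0.3·n) rows."""
    if ds.n < 10:
        raise ValueError("need at least 10 rows for a 7:3 split")
    n_test = int(round(0.3 * ds.n))
    perm = np.random.default_rng(seed).permutation(ds.n)
    return ds.subset(np.sort(perm[n_test:])), ds.subset(np.sort(perm[:n_test]))


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter grid for one model family."""

    family: str
    n_estimators: tuple[int, ...] = tuple(range(1, 11))
    max_depth: tuple[int, ...] = tuple(range(1, 7))
    activations: tuple[str, ...] = ("identity", "logistic", "tanh", "relu")
    solvers: tuple[str, ...] = ("lbfgs", "sgd", "adam")
    hidden_layers: tuple[int, int] = (16, 8)
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")

    def iter_params(self):
        """Enumerate grid points, simpler models first."""
        if self.family in ("adaboost", "random_forest"):
            for n_est, depth in itertools.product(self.n_estimators, self.max_depth):
                yield {"n_estimators": n_est, "max_depth": depth}
        else:
            for act, solver in itertools.product(self.activations, self.solvers):
                yield {"activation": act, "solver": solver,
                       "hidden_layer_sizes": self.hidden_layers,
                       "max_iter": self.max_iter}


def _make_estimator(family: str, params: dict, seed: int):
    if family == "adaboost":
        base = DecisionTreeRegressor(max_depth=params["max_depth"], random_state=seed)
        return AdaBoostRegressor(estimator=base, n_estimators=params["n_estimators"],
                                 random_state=seed)
    if family == "random_forest":
        return RandomForestRegressor(n_estimators=params["n_estimators"],
                                     max_depth=params["max_depth"], random_state=seed)
    if family == "bpnn":
        # the network needs standardized inputs and targets (trees do not)
        net = make_pipeline(StandardScaler(),
                            MLPRegressor(random_state=seed, **params))
        return TransformedTargetRegressor(regressor=net,
                                          transformer=StandardScaler())
    raise ValueError(f"unknown family {family!r}")


def regression_metrics(y_true: Sequence[float], y_pred: Sequence[float]
                       ) -> tuple[Optional[float], float, float]:
    """(R², MSE, MAE); R² is None (with a warning) for zero-variance targets."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("inputs must be equal-length and non-empty")
    resid = y_true - y_pred
    mse = float(np.mean(resid ** 2))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("zero-variance targets: R² undefined")
        return None, mse, mae
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return r2, mse, mae


@dataclass(frozen=True)
class CVCandidate:
    params: dict
    fold_metrics: tuple[dict, ...]      # per-fold {"r2", "mse", "mae"}
    mean_r2: float


@dataclass(frozen=True)
class GridSearchResult:
    family: str
    best: CVCandidate
    candidates: tuple[CVCandidate, ...]

    @property
    def best_params(self) -> dict:
        return self.best.params


def grid_search_cv(train: Dataset, grid: GridSpec, k: int = 10,
                   seed: int = 0) -> GridSearchResult:
    """Exhaustive grid search scored by mean k-fold CV R².

    Ties are broken toward the smaller model (fewer estimators, then
    shallower trees; for the network, earlier grid order).  Per-fold
    R²/MSE/MAE are retained for every candidate.
    """
    if k > train.n:
        raise ValueError("k exceeds the number of training rows")
    folds = list(KFold(n_splits=k, shuffle=True, random_state=seed).split(train.X))
    candidates = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for params in grid.iter_params():
            fold_metrics = []
            for tr_idx, va_idx in folds:
                est = _make_estimator(grid.family, params, seed)
                est.fit(train.X[tr_idx], train.y[tr_idx])
                pred = est.predict(train.X[va_idx])
                r2, mse, mae = regression_metrics(train.y[va_idx], pred)
                fold_metrics.append({"r2": r2, "mse": mse, "mae": mae})
            scores = [m["r2"] for m in fold_metrics if m["r2"] is not None]
            mean_r2 = float(np.mean(scores)) if scores else -np.inf
            candidates.append(CVCandidate(params=params,
                                          fold_metrics=tuple(fold_metrics),
                                          mean_r2=mean_r2))
    if not candidates:
        raise ValueError("empty hyperparameter grid")
    best = candidates[0]
    for cand in candidates[1:]:
        if cand.mean_r2 > best.mean_r2:
            best = cand  # strict improvement only: grid order = simpler first
    return GridSearchResult(family=grid.family, best=best,
                            candidates=tuple(candidates))


def fit_predict(family: str, params: dict, train: Dataset, test: Dataset,
                seed: int = 0) -> np.ndarray:
    """Refit on the full training set with the chosen parameters, score test.

    A non-converged network is reported with a warning and its partial fit
    is still used.
    """
    est = _make_estimator(family, params, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("always", ConvergenceWarning)
        est.fit(train.X, train.y)
    return est.predict(test.X)


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    lower_limit: float
    upper_limit: float
    outside_count: int
    n: int


def bland_altman(y_true: Sequence[float], y_pred: Sequence[float]) -> BlandAltman:
    """95% limits of agreement: mean(d) ± 1.96·SD(d), d = predicted − actual.

    SD is the population standard deviation.  Points strictly outside the
    limits are counted.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size < 2 or y_true.shape != y_pred.shape:
        raise ValueError("need two equal-length vectors of length >= 2")
    d = y_pred - y_true
    mean = float(d.mean())
    sd = float(d.std(ddof=0))
    lower, upper = mean - 1.96 * sd, mean + 1.96 * sd
    outside = int(np.sum((d < lower) | (d > upper)))
    return BlandAltman(mean_diff=mean, lower_limit=lower, upper_limit=upper,
                       outside_count=outside, n=d.size)


def pearson_matrix(table: pd.DataFrame, min_periods: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix.

    Pairs with fewer than ``min_periods`` complete rows, and zero-variance
    columns, come out as missing (NaN).
    """
    df = pd.DataFrame(table).astype(float)
    return df.corr(method="pearson", min_periods=min_periods)


@dataclass(frozen=True)
class RegressionReport:
    """Everything the evaluation protocol produces for one model family."""

    family: str
    best_params: dict
    cv_mean_r2: float
    fold_metrics: tuple[dict, ...]
    test_r2: Optional[float]
    test_mse: float
    test_mae: float
    predictions: np.ndarray
    actuals: np.ndarray
    agreement: BlandAltman
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "best_params": {k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in self.best_params.items()},
            "cv_mean_r2": self.cv_mean_r2,
            "fold_metrics": list(self.fold_metrics),
            "test_r2": self.test_r2,
            "test_mse": self.test_mse,
            "test_mae": self.test_mae,
            "predictions": self.predictions.tolist(),
            "actuals": self.actuals.tolist(),
            "bland_altman": {
                "mean_diff": self.agreement.mean_diff,
                "lower_limit": self.agreement.lower_limit,
                "upper_limit": self.agreement.upper_limit,
                "outside_count": self.agreement.outside_count,
            },
            "seed": self.seed,
        }


def evaluate_family(train: Dataset, test: Dataset, family: str,
                    k: int = 10, seed: int = 0,
                    grid: GridSpec | None = None) -> RegressionReport:
    """Grid search on the training set, refit, and report test performance."""
    grid = grid or GridSpec(family=family)
    search = grid_search_cv(train, grid, k=k, seed=seed)
    pred = fit_predict(family, search.best_params, train, test, seed=seed)
    r2, mse, mae = regression_metrics(test.y, pred)
    return RegressionReport(
        family=family, best_params=search.best_params,
        cv_mean_r2=search.best.mean_r2, fold_metrics=search.best.fold_metrics,
        test_r2=r2, test_mse=mse, test_mae=mae,
        predictions=pred, actuals=test.y, agreement=bland_altman(test.y, pred),
        seed=seed)
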
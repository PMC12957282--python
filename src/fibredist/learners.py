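"""Registry of the seven supervised learners with their tuning grids.

All learners share a uniform scikit-learn fit/predict contract on the
standardised predictor matrix, with the outcome (fibre diameter) in
nanometres.  The tuning grids are the fixed deterministic sets used for
model selection:

* linear: no hyperparameters;
* elastic net: mixing alpha in {0, 0.25, 0.5, 0.75, 1} crossed with a
  25-point logarithmic lambda grid on 1e-4 ... 1e1;
* decision tree: complexity parameter cp on 10 log-spaced points
  1e-4 ... 1e-1 (mapped to cost-complexity pruning on the outcome scale);
* MARS: degree in {1, 2} x nprune in {5, 10, 15, 20, 25};
* kNN: k in {3, 5, 7, 9, 11}, Euclidean, uniform weights;
* random forest: mtry 1..p x min node size {1, 5, 10}, 500 trees;
* RBF SVM: C in {0.25, 0.5, 1, 2, 4}, kernel width fixed by the
  median-pairwise-squared-distance heuristic (not tuned).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet, Ridge
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted

from .mars import MarsRegressor

LEARNER_NAMES = (
    "linear",
    "elastic_net",
    "decision_tree",
    "mars",
    "knn",
    "random_forest",
    "svm_rbf",
)

#: 25-point logarithmic lambda grid for the elastic net.
LAMBDA_GRID = np.logspace(-4, 1, 25)
#: 10-point logarithmic cp grid for the decision tree.
CP_GRID = np.logspace(-4, -1, 10)


def rbf_sigma_heuristic(X, seed: int = 0, max_rows: int = 100) -> float:
    """Kernel width sigma = 1 / median pairwise squared distance.

    Computed on a seeded subsample of at most ``max_rows`` rows; zero
    distances (duplicate rows) are excluded from the median.  With the RBF
    kernel written exp(-sigma * ||x - x'||^2), scaling X by c rescales
    sigma by 1/c^2.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 rows for the RBF width heuristic")
    rng = np.random.default_rng(seed)
    if X.shape[0] > max_rows:
        idx = rng.choice(X.shape[0], size=max_rows, replace=False)
        X = X[np.sort(idx)]
    sq = pdist(X, metric="sqeuclidean")
    sq = sq[sq > 0]
    if sq.size == 0:
        raise ValueError("degenerate design for RBF kernel: all rows identical")
    return float(1.0 / np.median(sq))


def _as_matrix(X) -> np.ndarray:
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(-1, 1)
    return arr


class LinearLearner(RegressorMixin, BaseEstimator):
    """Ordinary least squares via the pseudo-inverse.

    A rank-deficient design falls back to the minimum-norm least-squares
    solution with a logged warning rather than an error.
    """

    def fit(self, X, y):
        X = _as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        design = np.column_stack([np.ones(len(y)), X])
        coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        if rank < design.shape[1]:
            warnings.warn("singular design: using least-squares pseudo-solution")
        self.intercept_ = float(coef[0])
        self.coef_ = coef[1:]
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return _as_matrix(X) @ self.coef_ + self.intercept_


class ElasticNetLearner(RegressorMixin, BaseEstimator):
    """Elastic net with mixing parameter ``alpha`` and penalty ``lam``.

    ``alpha`` = 0 is pure ridge and is solved in closed form (with the
    penalty rescaled to match the coordinate-descent objective exactly);
    ``alpha`` = 1 is the lasso.  Coordinate-descent tolerance is 1e-7.
    """

    def __init__(self, alpha: float = 0.5, lam: float = 0.01):
        self.alpha = alpha
        self.lam = lam

    def fit(self, X, y):
        X = _as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        if self.alpha == 0:
            # ElasticNet objective: (1/2n)||r||^2 + lam*0.5*||w||^2
            # Ridge objective:      ||r||^2 + a||w||^2  =>  a = n * lam
            self._model_ = Ridge(alpha=len(y) * self.lam, solver="cholesky").fit(X, y)
        else:
            self._model_ = ElasticNet(
                alpha=self.lam, l1_ratio=self.alpha, tol=1e-7, max_iter=100_000
            ).fit(X, y)
        self.coef_ = self._model_.coef_
        self.intercept_ = float(self._model_.intercept_)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "_model_")
        return self._model_.predict(_as_matrix(X))


class CartLearner(RegressorMixin, BaseEstimator):
    """Regression tree with rpart-style relative complexity parameter.

    ``cp`` is scale-free: it is multiplied by the training-outcome variance
    to obtain scikit-learn's absolute ``ccp_alpha`` pruning threshold.
    """

    def __init__(self, cp: float = 0.01, random_state: int = 0):
        self.cp = cp
        self.random_state = random_state

    def fit(self, X, y):
        X = _as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        self._model_ = DecisionTreeRegressor(
            ccp_alpha=self.cp * float(np.var(y)), random_state=self.random_state
        ).fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "_model_")
        return self._model_.predict(_as_matrix(X))


class KNNLearner(RegressorMixin, BaseEstimator):
    """k-nearest-neighbour regression, Euclidean, uniform weights.

    Prediction is the mean outcome of the k nearest training rows; ties in
    neighbour distance are broken by training-row order (stable sort), which
    makes predictions fully deterministic.
    """

    def __init__(self, k: int = 5):
        self.k = k

    def fit(self, X, y):
        X = _as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) < self.k:
            raise ValueError(f"kNN with k={self.k} needs at least {self.k} training rows")
        self.X_ = X
        self.y_ = y
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "X_")
        X = _as_matrix(X)
        if X.shape[0] == 0:
            return np.empty(0)
        out = np.empty(X.shape[0])
        # chunked to bound the distance-matrix memory
        chunk = max(1, int(2e6 // max(1, len(self.y_))))
        for start in range(0, X.shape[0], chunk):
            d = cdist(X[start:start + chunk], self.X_)
            order = np.argsort(d, axis=1, kind="stable")[:, : self.k]
            out[start:start + chunk] = self.y_[order].mean(axis=1)
        return out


class RandomForestLearner(RegressorMixin, BaseEstimator):
    """Random forest with mtry / minimum node size / tree count."""

    def __init__(self, mtry: int = 2, min_node_size: int = 5,
                 num_trees: int = 500, random_state: int = 0):
        self.mtry = mtry
        self.min_node_size = min_node_size
        self.num_trees = num_trees
        self.random_state = random_state

    def fit(self, X, y):
        X = _as_matrix(X)
        self._model_ = RandomForestRegressor(
            n_estimators=self.num_trees,
            max_features=min(self.mtry, X.shape[1]),
            min_samples_leaf=self.min_node_size,
            random_state=self.random_state,
            n_jobs=1,
        ).fit(X, np.asarray(y, dtype=float).ravel())
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "_model_")
        return self._model_.predict(_as_matrix(X))


class SVMRBFLearner(RegressorMixin, BaseEstimator):
    """RBF support vector regression; sigma fixed by heuristic, C tuned."""

    def __init__(self, C: float = 1.0, sigma: float | None = None, random_state: int = 0):
        self.C = C
        self.sigma = sigma
        self.random_state = random_state

    def fit(self, X, y):
        X = _as_matrix(X)
        self.sigma_ = self.sigma if self.sigma is not None else rbf_sigma_heuristic(
            X, seed=self.random_state
        )
        self._model_ = SVR(kernel="rbf", C=self.C, gamma=self.sigma_, epsilon=0.1).fit(
            X, np.asarray(y, dtype=float).ravel()
        )
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "_model_")
        X = _as_matrix(X)
        if X.shape[0] == 0:
            return np.empty(0)
        return self._model_.predict(X)


_FACTORIES = {
    "linear": lambda config, seed: LinearLearner(),
    "elastic_net": lambda config, seed: ElasticNetLearner(**config),
    "decision_tree": lambda config, seed: CartLearner(random_state=seed, **config),
    "mars": lambda config, seed: MarsRegressor(**config),
    "knn": lambda config, seed: KNNLearner(**config),
    "random_forest": lambda config, seed: RandomForestLearner(random_state=seed, **config),
    "svm_rbf": lambda config, seed: SVMRBFLearner(random_state=seed, **config),
}


def make_grid(name: str, p: int, n: int) -> list[dict]:
    """Deterministic hyperparameter grid for learner ``name``.

    ``p`` is the number of (kept) predictors, ``n`` the number of training
    rows; only the random-forest grid depends on ``p``.
    """
    if p < 1 or n < 2:
        raise ValueError("need p >= 1 and n >= 2")
    if name == "linear":
        return [{}]
    if name == "elastic_net":
        return [
            {"alpha": a, "lam": float(l)}
            for a in (0.0, 0.25, 0.5, 0.75, 1.0)
            for l in LAMBDA_GRID
        ]
    if name == "decision_tree":
        return [{"cp": float(cp)} for cp in CP_GRID]
    if name == "mars":
        return [
            {"degree": d, "nprune": np_}
            for d in (1, 2)
            for np_ in (5, 10, 15, 20, 25)
        ]
    if name == "knn":
        return [{"k": k} for k in (3, 5, 7, 9, 11)]
    if name == "random_forest":
        return [
            {"mtry": m, "min_node_size": s, "num_trees": 500}
            for m in range(1, p + 1)
            for s in (1, 5, 10)
        ]
    if name == "svm_rbf":
        return [{"C": c} for c in (0.25, 0.5, 1.0, 2.0, 4.0)]
    raise ValueError(f"unknown learner {name!r}; known: {list(LEARNER_NAMES)}")


def make_estimator(name: str, config: dict | None = None, seed: int = 0):
    """Build an unfitted estimator for learner ``name`` with ``config``."""
    if name not in _FACTORIES:
        raise ValueError(f"unknown learner {name!r}; known: {list(LEARNER_NAMES)}")
    return _FACTORIES[name](dict(config or {}), seed)


def coefficient_table(model, feature_names: list[str]) -> pd.DataFrame | None:
    """Coefficient table for transparent learners; None otherwise."""
    if isinstance(model, (LinearLearner, ElasticNetLearner)):
        terms = ["(intercept)"] + list(feature_names)
        estimates = np.concatenate([[model.intercept_], model.coef_])
        return pd.DataFrame({"term": terms, "estimate": estimates})
    return None


def fit(name_or_spec, config: dict, X, y, seed: int = 0):
    """Fit one learner configuration on standardised predictors.

    Returns the fitted estimator; transparent learners (linear, elastic net)
    additionally carry a ``coefficients_table_`` DataFrame.
    """
    name = getattr(name_or_spec, "name", name_or_spec)
    model = make_estimator(name, config, seed)
    model.fit(X, y)
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
    else:
        names = [f"x{i}" for i in range(_as_matrix(X).shape[1])]
    table = coefficient_table(model, names)
    if table is not None:
        model.coefficients_table_ = table
    return model


def predict(model, X) -> np.ndarray:
    """Predict fibre diameters (nm), one per row; empty input -> empty output."""
    if hasattr(X, "shape") and X.shape[0] == 0:
        return np.empty(0)
    yhat = np.asarray(model.predict(X), dtype=float)
    if not np.all(np.isfinite(yhat)):
        raise ValueError("non-finite prediction produced")
    return yhat
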
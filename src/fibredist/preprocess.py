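"""Leakage-free per-fold standardisation recipe for the six predictors.

The recipe drops zero-variance predictors and z-normalises the rest using
statistics computed on the fitting (training) rows only; the outcome stays
in nanometres.  It is a scikit-learn transformer so it composes with
``sklearn.pipeline.Pipeline`` and is refit inside every resampling split.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import PREDICTORS


class StandardRecipe(TransformerMixin, BaseEstimator):
    """Zero-variance removal followed by z-normalisation.

    Parameters
    ----------
    features : list of str, optional
        Predictor columns the recipe considers.  Defaults to the six
        canonical process parameters.

    Attributes
    ----------
    kept_features_ : list of str
        Features retained after zero-variance removal (exact equality of all
        fitted values counts as zero variance; near-zero variance is kept).
    means_, sds_ : ndarray
        Per-kept-feature training mean and sample (n-1) standard deviation.
    """

    def __init__(self, features: list[str] | None = None):
        self.features = features

    def _resolve_features(self, X) -> list[str]:
        if self.features is not None:
            return list(self.features)
        if isinstance(X, pd.DataFrame):
            return [c for c in PREDICTORS if c in X.columns] or list(X.columns)
        return [f"x{i}" for i in range(np.asarray(X).shape[1])]

    def _as_frame(self, X, features) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            missing = [f for f in features if f not in X.columns]
            if missing:
                raise KeyError(f"missing predictor columns: {missing}")
            return X[features]
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(features):
            raise ValueError(f"expected {len(features)} predictor columns, got {arr.shape}")
        return pd.DataFrame(arr, columns=features)

    def fit(self, X, y=None):
        features = self._resolve_features(X)
        frame = self._as_frame(X, features)
        if len(frame) < 2:
            raise ValueError("need at least 2 rows to fit a standardisation recipe")
        kept, means, sds = [], [], []
        for col in features:
            values = frame[col].to_numpy(dtype=float)
            if np.all(values == values[0]):  # exact zero variance
                continue
            kept.append(col)
            means.append(float(np.mean(values)))
            sds.append(float(np.std(values, ddof=1)))
        if not kept:
            raise ValueError("no informative predictors: all columns are constant")
        self.feature_names_in_ = np.asarray(features, dtype=object)
        self.kept_features_ = kept
        self.means_ = np.asarray(means)
        self.sds_ = np.asarray(sds)
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "kept_features_"):
            raise RuntimeError("recipe is not fitted")
        frame = self._as_frame(X, list(self.feature_names_in_))
        missing = [f for f in self.kept_features_ if f not in frame.columns]
        if missing:
            raise KeyError(f"missing kept features: {missing}")
        out = (frame[self.kept_features_].to_numpy(dtype=float) - self.means_) / self.sds_
        return pd.DataFrame(out, columns=self.kept_features_, index=frame.index)

    def inverse_transform(self, Z) -> pd.DataFrame:
        """Undo the affine map on kept features (audit/diagnostic use)."""
        arr = np.asarray(Z, dtype=float) * self.sds_ + self.means_
        return pd.DataFrame(arr, columns=self.kept_features_)

    def to_json(self) -> str:
        """Serialise fitted statistics for report auditability."""
        return json.dumps(
            {
                "kept_features": self.kept_features_,
                "means": self.means_.tolist(),
                "sds": self.sds_.tolist(),
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "StandardRecipe":
        state = json.loads(payload)
        recipe = cls(features=list(state["kept_features"]))
        recipe.feature_names_in_ = np.asarray(state["kept_features"], dtype=object)
        recipe.kept_features_ = list(state["kept_features"])
        recipe.means_ = np.asarray(state["means"])
        recipe.sds_ = np.asarray(state["sds"])
        return recipe


def fit_recipe(train_rows, features: list[str] | None = None) -> StandardRecipe:
    """Fit a :class:`StandardRecipe` on training rows only."""
    return StandardRecipe(features=features).fit(train_rows)


def apply_recipe(recipe: StandardRecipe, rows) -> pd.DataFrame:
    """Apply a fitted recipe; out-of-range rows are transformed, not clipped."""
    return recipe.transform(rows)
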
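"""Interpretability diagnostics: importance, Shapley values, correlations,
and response surfaces.

Variable importance is computed model-agnostically by permutation (mean
increase in RMSE over repeated column shuffles, rescaled so the top feature
scores 100), which applies uniformly across all seven learners; transparent
learners additionally expose their coefficient table.  Shapley attributions
are Monte-Carlo estimates over a background sample of at most 200 rows with
a configurable number of simulations per feature, in nanometres, so a
feature's value states how much it pushes the prediction above or below the
background-average output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import OUTCOME, PREDICTORS, MetaDataset

DEFAULT_NSIM = 50
MAX_BACKGROUND = 200


def variable_importance(model, X, y, seed: int = 0, n_repeats: int = 10,
                        top: int = 20) -> pd.Series:
    """Permutation importance, rescaled to [0, 100] and ranked.

    For each feature, that column of ``X`` is shuffled ``n_repeats`` times
    and the mean increase in RMSE over the unpermuted baseline is recorded;
    negative increases are clipped to zero and scores rescaled so the
    maximum is 100.  Ties are broken alphabetically.  Returns the top
    ``top`` features as a Series.
    """
    X = pd.DataFrame(X).copy()
    y = np.asarray(y, dtype=float).ravel()
    if len(X) < 10:
        raise ValueError("need at least 10 rows for permutation importance")
    if np.all(y == y[0]):
        raise ValueError("degenerate outcome: importance undefined")
    rng = np.random.default_rng(seed)
    base_rmse = float(np.sqrt(np.mean((y - np.asarray(model.predict(X))) ** 2)))
    scores = {}
    for col in X.columns:
        increases = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[col] = rng.permutation(Xp[col].to_numpy())
            rmse = float(np.sqrt(np.mean((y - np.asarray(model.predict(Xp))) ** 2)))
            increases.append(rmse - base_rmse)
        scores[str(col)] = max(0.0, float(np.mean(increases)))
    top_score = max(scores.values())
    if top_score > 0:
        scores = {k: 100.0 * v / top_score for k, v in scores.items()}
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[:top]
    return pd.Series(dict(ranked), name="importance")


@dataclass
class AttributionSet:
    """Monte-Carlo Shapley attributions for a set of explained instances."""

    shap: pd.DataFrame  # rows = instances, cols = features, values in nm
    baseline: float  # mean model output on the background (nm)
    nsim: int
    seed: int

    @property
    def mean_abs(self) -> pd.Series:
        """Features ordered by mean absolute attribution (global summary)."""
        return self.shap.abs().mean().sort_values(ascending=False)

    def top_features(self, k: int = 6) -> list[str]:
        """The k most influential features for the summary dot plot."""
        return list(self.mean_abs.index[:k])


def shap_values(model, instances, background, nsim: int = DEFAULT_NSIM,
                seed: int = 0) -> AttributionSet:
    """Monte-Carlo Shapley values per instance and feature.

    Each simulation samples a random feature permutation and a random
    background row z; the attribution of feature j is the mean difference
    between predictions on two hybrid rows that agree on the features
    preceding j (taken from the instance) and differ only in whether j
    itself comes from the instance or from z.  For an additive model this
    converges to beta_j * (x_j - mean background_j).
    """
    instances = pd.DataFrame(instances)
    background = pd.DataFrame(background)
    if len(background) < 2:
        raise ValueError("background must contain at least 2 rows")
    if len(background) > MAX_BACKGROUND:
        background = background.iloc[:MAX_BACKGROUND]
    if nsim < 1:
        raise ValueError("nsim must be >= 1")
    cols = list(instances.columns)
    p = len(cols)
    rng = np.random.default_rng(seed)
    bg = background[cols].to_numpy(dtype=float)
    inst = instances[cols].to_numpy(dtype=float)
    n_inst = inst.shape[0]

    phi = np.zeros((n_inst, p))
    for s in range(nsim):
        perm = rng.permutation(p)
        z_idx = rng.integers(0, bg.shape[0], size=n_inst)
        z = bg[z_idx]
        # walk the permutation replacing background features by instance ones
        rows_plus = []
        rows_minus = []
        current = z.copy()
        order = []
        for j in perm:
            before = current.copy()
            current = current.copy()
            current[:, j] = inst[:, j]
            rows_minus.append(before)
            rows_plus.append(current)
            order.append(j)
        stacked = np.vstack(rows_plus + rows_minus)
        preds = np.asarray(
            model.predict(pd.DataFrame(stacked, columns=cols)), dtype=float
        )
        preds_plus = preds[: p * n_inst].reshape(p, n_inst)
        preds_minus = preds[p * n_inst:].reshape(p, n_inst)
        for pos, j in enumerate(order):
            phi[:, j] += preds_plus[pos] - preds_minus[pos]
    phi /= nsim
    baseline = float(
        np.mean(np.asarray(model.predict(pd.DataFrame(bg, columns=cols)), dtype=float))
    )
    return AttributionSet(
        shap=pd.DataFrame(phi, columns=cols, index=instances.index),
        baseline=baseline,
        nsim=nsim,
        seed=seed,
    )


def correlation_matrix(ds) -> pd.DataFrame:
    """Pearson correlations over the six predictors plus the diameter.

    Constant columns yield missing correlations (NaN) off the diagonal; the
    diagonal is 1 for non-constant columns.
    """
    df = ds.df if isinstance(ds, MetaDataset) else pd.DataFrame(ds)
    cols = [c for c in PREDICTORS + [OUTCOME] if c in df.columns]
    if len(df) < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    return df[cols].astype(float).corr(method="pearson")


def response_surface(model, feature_a: str, feature_b: str, grid_size: int,
                     ds) -> pd.DataFrame:
    """Predicted diameter over a grid of two features, others at medians.

    ``model`` must accept raw predictor rows (e.g. a recipe+learner
    pipeline).  The grid spans the observed [min, max] of each feature in
    the polymer subset ``ds``; all remaining predictors are fixed at their
    subset medians.  Returns tidy (a, b, predicted_diameter) triples.
    """
    df = ds.df if isinstance(ds, MetaDataset) else pd.DataFrame(ds)
    for feat in (feature_a, feature_b):
        if feat not in PREDICTORS:
            raise ValueError(f"{feat!r} is not a model predictor")
        if np.all(df[feat].to_numpy() == df[feat].to_numpy()[0]):
            raise ValueError(f"{feat!r} has zero variance in this subset")
    a_grid = np.linspace(df[feature_a].min(), df[feature_a].max(), grid_size)
    b_grid = np.linspace(df[feature_b].min(), df[feature_b].max(), grid_size)
    medians = df[PREDICTORS].median()
    aa, bb = np.meshgrid(a_grid, b_grid, indexing="ij")
    grid = pd.DataFrame(
        {c: np.full(grid_size**2, medians[c]) for c in PREDICTORS}
    )
    grid[feature_a] = aa.ravel()
    grid[feature_b] = bb.ravel()
    preds = np.asarray(model.predict(grid), dtype=float)
    return pd.DataFrame(
        {feature_a: aa.ravel(), feature_b: bb.ravel(), "predicted_diameter": preds}
    )
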
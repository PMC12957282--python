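"""Nested cross-validation with leave-one-study-out outer folds.

The outer loop holds out all rows of one study per fold (K folds for K
studies), which estimates generalisation to unseen experimental batches and
blocks leakage from near-replicate conditions within a study.  An inner loop
of row-level 5-fold cross-validation with two repeats tunes each learner's
hyperparameters on the outer-training rows only; the standardisation recipe
is refit inside every split.  Aggregating the held-out predictions yields
the out-of-fold empirical distribution of modelled diameters and the
residual pool used for bootstrap predictive distributions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedKFold

from . import learners as L
from .io import OUTCOME, PREDICTORS, MetaDataset
from .preprocess import StandardRecipe

log = logging.getLogger(__name__)


@dataclass
class LearnerSpec:
    """A learner name, its tuning grid, and a base seed."""

    name: str
    grid: list[dict]
    seed: int = 0

    @classmethod
    def default(cls, name: str, p: int, n: int, seed: int = 0) -> "LearnerSpec":
        return cls(name=name, grid=L.make_grid(name, p, n), seed=seed)


@dataclass
class FoldPlan:
    """Leave-one-study-out outer folds plus the inner resampling spec."""

    outer_folds: list[tuple[tuple[str, ...], str]]
    inner_k: int = 5
    inner_repeats: int = 2
    seed: int = 0


@dataclass
class CVResult:
    """Out-of-fold predictions, residuals, and fold-wise metrics."""

    oof_pred: pd.Series
    oof_resid: pd.Series
    per_fold_metrics: pd.DataFrame  # columns: study, n, r2, rmse, mae
    summary: dict  # metric -> (mean, sd) across folds
    chosen_configs: dict = field(default_factory=dict)  # study -> config

    def to_frame(self, ds: MetaDataset) -> pd.DataFrame:
        """One row per record: study_id, observed, oof_pred, resid."""
        return pd.DataFrame(
            {
                "study_id": ds.df["study_id"].to_numpy(),
                "observed": ds.df[OUTCOME].to_numpy(),
                "oof_pred": self.oof_pred.to_numpy(),
                "resid": self.oof_resid.to_numpy(),
            }
        )


def compute_metrics(y, yhat) -> tuple[float, float, float]:
    """(R^2, RMSE, MAE) between observed and predicted diameters (nm).

    R^2 = 1 - SSE/SST and may be negative; with a constant observed vector
    SST is zero, R^2 is undefined and returned as NaN with a warning, while
    RMSE and MAE are still computed.
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if len(y) != len(yhat) or len(y) < 2:
        raise ValueError("need equal-length vectors with n >= 2")
    err = y - yhat
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        warnings.warn("constant observed outcome: R^2 undefined, reported as NaN")
        return (float("nan"), rmse, mae)
    r2 = 1.0 - float(np.sum(err**2)) / sst
    return (r2, rmse, mae)


def make_outer_folds(ds: MetaDataset, seed: int = 0) -> FoldPlan:
    """One outer fold per study, ordered deterministically by study_id."""
    studies = ds.studies
    if len(studies) < 2:
        raise ValueError(
            "cannot assess cross-study generalisation: need at least 2 distinct studies"
        )
    folds = [
        (tuple(s for s in studies if s != test), test)
        for test in studies
    ]
    return FoldPlan(outer_folds=folds, seed=seed)


def _child_seed(seed: int, *parts: int) -> int:
    """Deterministic child seed below 2**31 derived from a run seed."""
    return int(np.random.SeedSequence([seed, *parts]).generate_state(1)[0] % (2**31))


def tune(
    spec: LearnerSpec,
    train_rows: pd.DataFrame,
    inner_k: int = 5,
    inner_repeats: int = 2,
    seed: int = 0,
) -> dict:
    """Select the grid configuration minimising mean inner-resample RMSE.

    ``train_rows`` holds the raw (unstandardised) predictors plus outcome.
    Within each of the k x repeats inner splits the recipe is refit on the
    inner-training rows only.  Ties are broken by grid order; a grid of size
    one is returned without search.  If there are fewer rows than folds the
    inner k is reduced to the largest feasible value >= 2 with a warning.
    """
    if len(spec.grid) == 1:
        return dict(spec.grid[0])
    n = len(train_rows)
    k = inner_k
    if n < 2 * k:
        k = max(2, n // 2)
        log.warning("reducing inner folds from %d to %d for n=%d", inner_k, k, n)
    X = train_rows[PREDICTORS]
    y = train_rows[OUTCOME].to_numpy(dtype=float)
    splitter = RepeatedKFold(n_splits=k, n_repeats=inner_repeats, random_state=seed)
    sums = np.zeros(len(spec.grid))
    counts = np.zeros(len(spec.grid))
    for split_idx, (tr, va) in enumerate(splitter.split(X)):
        recipe = StandardRecipe().fit(X.iloc[tr])
        Z_tr = recipe.transform(X.iloc[tr])
        Z_va = recipe.transform(X.iloc[va])
        for ci, config in enumerate(spec.grid):
            model = L.make_estimator(
                spec.name, config, seed=_child_seed(seed, 1, split_idx, ci)
            )
            try:
                model.fit(Z_tr, y[tr])
                yhat = model.predict(Z_va)
            except Exception as exc:  # e.g. k > n_train for kNN
                log.debug("config %r failed on inner split %d: %s", config, split_idx, exc)
                sums[ci] += np.inf
                counts[ci] += 1
                continue
            sums[ci] += float(np.sqrt(np.mean((y[va] - yhat) ** 2)))
            counts[ci] += 1
    mean_rmse = sums / np.maximum(counts, 1)
    best = int(np.argmin(mean_rmse))  # argmin takes the first minimiser: grid order
    return dict(spec.grid[best])


def nested_cv(
    ds: MetaDataset,
    spec: LearnerSpec,
    seed: int = 0,
    inner_k: int = 5,
    inner_repeats: int = 2,
) -> CVResult:
    """Leave-one-study-out nested cross-validation for one learner.

    Per outer fold: the recipe is fit on the outer-training rows only, the
    inner loop tunes on the outer-training rows only, the winning
    configuration is refit on the full outer-training set, and the held-out
    study's rows receive their single out-of-fold prediction.  Fold metrics
    are summarised as mean +/- sd across folds.
    """
    plan = make_outer_folds(ds, seed=seed)
    df = ds.df
    study = df["study_id"].astype(str).to_numpy()
    y_all = df[OUTCOME].to_numpy(dtype=float)
    oof = np.full(len(df), np.nan)
    rows = []
    chosen: dict[str, dict] = {}
    for fold_idx, (train_studies, test_study) in enumerate(plan.outer_folds):
        test_mask = study == test_study
        train_rows = df.loc[~test_mask]
        fold_seed = _child_seed(seed, fold_idx)
        try:
            config = tune(
                spec, train_rows, inner_k=inner_k, inner_repeats=inner_repeats, seed=fold_seed
            )
            recipe = StandardRecipe().fit(train_rows[PREDICTORS])
            model = L.fit(
                spec.name,
                config,
                recipe.transform(train_rows[PREDICTORS]),
                train_rows[OUTCOME].to_numpy(dtype=float),
                seed=fold_seed,
            )
            yhat = L.predict(model, recipe.transform(df.loc[test_mask, PREDICTORS]))
        except Exception as exc:
            raise RuntimeError(
                f"learner {spec.name!r} failed on outer fold holding out study "
                f"{test_study!r}: {exc}"
            ) from exc
        oof[test_mask] = yhat
        chosen[test_study] = config
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # single-study folds may have constant y
            r2, rmse, mae = compute_metrics(y_all[test_mask], yhat) if test_mask.sum() >= 2 \
                else (float("nan"), float(np.abs(y_all[test_mask] - yhat).mean()),
                      float(np.abs(y_all[test_mask] - yhat).mean()))
        rows.append({"study": test_study, "n": int(test_mask.sum()),
                     "r2": r2, "rmse": rmse, "mae": mae})
    per_fold = pd.DataFrame(rows)
    summary = {}
    for metric in ("r2", "rmse", "mae"):
        vals = per_fold[metric].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        summary[metric] = (
            float(np.mean(finite)) if finite.size else float("nan"),
            float(np.std(finite, ddof=1)) if finite.size > 1 else 0.0,
        )
    resid = y_all - oof
    return CVResult(
        oof_pred=pd.Series(oof, index=df.index, name="oof_pred"),
        oof_resid=pd.Series(resid, index=df.index, name="oof_resid"),
        per_fold_metrics=per_fold,
        summary=summary,
        chosen_configs=chosen,
    )


def modal_config(result: CVResult) -> dict:
    """Most frequent winning configuration across folds (ties: first seen)."""
    counts: dict[str, tuple[int, dict]] = {}
    order = []
    for config in result.chosen_configs.values():
        key = repr(sorted(config.items()))
        if key not in counts:
            counts[key] = (0, config)
            order.append(key)
        counts[key] = (counts[key][0] + 1, config)
    best_key = max(order, key=lambda k: counts[k][0])
    return dict(counts[best_key][1])
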
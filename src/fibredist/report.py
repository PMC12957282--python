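"""End-to-end prediction runs and the auditable Excel report.

``run_predict`` executes the full pipeline for one user query — polymer
subset, nested cross-validation, final refit, point prediction, residual
bootstrap, interpretability diagnostics, range check and solvent
recommendation — and returns a :class:`RunRecord`.  ``write_report`` emits
the structured workbook (Summary, Out_of_Range, CV_Predictions,
Prediction_Distribution, Metrics, Coefficients, Variable_Importance,
SHAP_Summary, Correlation_Matrix) with embedded figures.
"""

from __future__ import annotations

import io as _io
import logging
import time
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from openpyxl import Workbook
from openpyxl.drawing.image import Image as XLImage
from openpyxl.utils.dataframe import dataframe_to_rows

from . import __version__
from .advisor import DEFAULT_TOP_N, DEFAULT_W, QuerySettings, RangeCheck, Recommendation, range_check, recommend_solvents
from .distribution import DEFAULT_B, PredictiveDistribution, bootstrap_predictive
from .evaluation import CVResult, LearnerSpec, _child_seed, modal_config, nested_cv
from .interpret import AttributionSet, correlation_matrix, shap_values, variable_importance
from .io import OUTCOME, PREDICTORS, MetaDataset, load_dataset, subset_polymer
from .learners import coefficient_table, fit as fit_learner, make_grid
from .preprocess import StandardRecipe

log = logging.getLogger(__name__)

SHEETS = [
    "Summary",
    "Out_of_Range",
    "CV_Predictions",
    "Prediction_Distribution",
    "Metrics",
    "Coefficients",
    "Variable_Importance",
    "SHAP_Summary",
    "Correlation_Matrix",
]

NO_COEF_MARKER = "no transparent coefficients for this learner"


@dataclass
class PredictionPipeline:
    """A fitted recipe + learner pair predicting from raw predictor rows."""

    recipe: StandardRecipe
    model: object

    def predict(self, X) -> np.ndarray:
        frame = pd.DataFrame(X)
        return np.asarray(self.model.predict(self.recipe.transform(frame)), dtype=float)


@dataclass
class RunRecord:
    """Everything one prediction run produced, ready for the workbook."""

    query: QuerySettings
    learner: str
    config: dict
    y_hat: float
    predictive: PredictiveDistribution
    cv: CVResult
    cv_table: pd.DataFrame
    attributions: AttributionSet
    importance: pd.Series
    coefficients: pd.DataFrame | None
    recommendation: Recommendation
    ranges: RangeCheck
    correlations: pd.DataFrame
    pipeline: PredictionPipeline
    seed: int
    version: str = __version__
    timings: dict = field(default_factory=dict)


def run_predict(
    dataset: MetaDataset | str,
    query: QuerySettings,
    learner: str = "random_forest",
    seed: int = 0,
    B: int = DEFAULT_B,
    w: float = DEFAULT_W,
    top_n: int = DEFAULT_TOP_N,
    grid: list[dict] | None = None,
    nsim: int = 50,
) -> RunRecord:
    """Run the full prediction pipeline for one query; deterministic in seed.

    ``grid`` optionally overrides the learner's tuning grid (e.g. a
    singleton configuration for compute-constrained runs).
    """
    t0 = time.perf_counter()
    timings: dict[str, float] = {}
    query.validate()  # validation errors surface before any fitting
    log.info("WAIT ... PROCESSING")
    ds = load_dataset(dataset) if isinstance(dataset, str) else dataset
    sub = subset_polymer(ds, query.polymer)
    X_raw = sub.df[PREDICTORS]
    y = sub.df[OUTCOME].to_numpy(dtype=float)
    spec = LearnerSpec(
        name=learner,
        grid=grid if grid is not None else make_grid(learner, len(PREDICTORS), len(sub)),
        seed=seed,
    )
    cv = nested_cv(sub, spec, seed=seed)
    timings["nested_cv_s"] = time.perf_counter() - t0

    t1 = time.perf_counter()
    config = modal_config(cv)
    recipe = StandardRecipe().fit(X_raw)
    model = fit_learner(learner, config, recipe.transform(X_raw), y,
                        seed=_child_seed(seed, 999))
    pipeline = PredictionPipeline(recipe=recipe, model=model)
    y_hat = float(pipeline.predict(query.as_frame())[0])
    predictive = bootstrap_predictive(
        y_hat, cv.oof_resid.to_numpy(), B=B, seed=_child_seed(seed, 1000)
    )
    timings["final_fit_s"] = time.perf_counter() - t1

    t2 = time.perf_counter()
    rng = np.random.default_rng(_child_seed(seed, 1001))
    shuffled = X_raw.iloc[rng.permutation(len(X_raw))]
    background = shuffled.iloc[: min(200, len(shuffled))]
    instances = background.iloc[: min(50, len(background))]
    attributions = shap_values(pipeline, instances, background, nsim=nsim,
                               seed=_child_seed(seed, 1002))
    importance = variable_importance(pipeline, X_raw, y, seed=_child_seed(seed, 1003))
    coefs = coefficient_table(model, recipe.kept_features_)
    timings["interpret_s"] = time.perf_counter() - t2

    record = RunRecord(
        query=query,
        learner=learner,
        config=config,
        y_hat=y_hat,
        predictive=predictive,
        cv=cv,
        cv_table=cv.to_frame(sub),
        attributions=attributions,
        importance=importance,
        coefficients=coefs,
        recommendation=recommend_solvents(query, y_hat, sub, w=w, N=top_n),
        ranges=range_check(query, sub),
        correlations=correlation_matrix(sub),
        pipeline=pipeline,
        seed=seed,
        timings=timings,
    )
    log.info("RESULTS ready: y_hat=%.3f nm (learner=%s)", y_hat, learner)
    for stage, seconds in timings.items():
        log.info("stage %s: %.2f s", stage, seconds)
    return record


# --------------------------------------------------------------------------
# workbook writing

def _write_df(ws, df: pd.DataFrame, title: str | None = None) -> None:
    if title:
        ws.append([title])
    for row in dataframe_to_rows(df, index=False, header=True):
        ws.append([None if isinstance(v, float) and np.isnan(v) else v for v in row])


def _figure_png(fig) -> _io.BytesIO:
    buf = _io.BytesIO()
    fig.savefig(buf, format="png", dpi=110, bbox_inches="tight")
    plt.close(fig)
    buf.seek(0)
    return buf


def _embed(ws, fig, anchor: str) -> None:
    image = XLImage(_figure_png(fig))
    ws.add_image(image, anchor)


def _fig_distribution(run: RunRecord):
    fig, ax = plt.subplots(figsize=(6, 4))
    draws = run.predictive.draws
    if np.ptp(draws) <= 1e-9 * max(1.0, float(np.abs(draws).max())):
        # (near-)degenerate distribution: single spike
        ax.hist(draws, bins=1, range=(draws[0] - 1.0, draws[0] + 1.0),
                color="#4878a8", alpha=0.8)
    else:
        ax.hist(draws, bins=20, color="#4878a8", alpha=0.8)
    ax.axvline(run.y_hat, color="black", linestyle=":", linewidth=2)
    ax.annotate(f"prediction {run.y_hat:.1f} nm", xy=(run.y_hat, ax.get_ylim()[1] * 0.9),
                rotation=90, va="top", ha="right", fontsize=8)
    ax.set_xlabel("predicted fibre diameter (nm)")
    ax.set_ylabel("count")
    ax.set_title("Residual-bootstrap predictive distribution")
    return fig

def _fig_pred_obs(run: RunRecord):
    fig, ax = plt.subplots(figsize=(5, 5))
    obs = run.cv_table["observed"]
    pred = run.cv_table["oof_pred"]
    ax.scatter(obs, pred, s=8, alpha=0.5)
    lims = [min(obs.min(), pred.min()), max(obs.max(), pred.max())]
    ax.plot(lims, lims, color="black", linewidth=1)
    ax.set_xlabel("observed diameter (nm)")
    ax.set_ylabel("out-of-fold predicted (nm)")
    ax.set_title("Predicted vs observed")
    return fig

def _fig_importance(run: RunRecord):
    fig, ax = plt.subplots(figsize=(5, 4))
    run.importance.iloc[::-1].plot.barh(ax=ax, color="#4878a8")
    ax.set_xlabel("permutation importance (0-100)")
    ax.set_title("Variable importance")
    return fig

def _fig_shap(run: RunRecord):
    fig, ax = plt.subplots(figsize=(6, 4))
    rng = np.random.default_rng(0)
    top = run.attributions.top_features(6)
    for i, feat in enumerate(top):
        vals = run.attributions.shap[feat].to_numpy()
        ax.scatter(vals, np.full_like(vals, i) + rng.uniform(-0.15, 0.15, vals.size),
                   s=10, alpha=0.6)
    ax.set_yticks(range(len(top)), top)
    ax.axvline(0, color="grey", linewidth=0.8)
    ax.set_xlabel("SHAP value (nm)")
    ax.set_title("SHAP summary (top 6 features)")
    return fig

def _fig_corr(run: RunRecord):
    fig, ax = plt.subplots(figsize=(5.5, 5))
    mat = run.correlations.to_numpy(dtype=float)
    im = ax.imshow(mat, vmin=-1, vmax=1, cmap="RdBu_r")
    labels = list(run.correlations.columns)
    ax.set_xticks(range(len(labels)), labels, rotation=45, ha="right", fontsize=7)
    ax.set_yticks(range(len(labels)), labels, fontsize=7)
    for i in range(len(labels)):
        for j in range(len(labels)):
            if np.isfinite(mat[i, j]):
                ax.text(j, i, f"{mat[i, j]:.2f}", ha="center", va="center", fontsize=6)
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title("Correlation heat map")
    return fig


def write_report(run: RunRecord, path) -> None:
    """Write the full Excel workbook for a completed run."""
    wb = Workbook()
    wb.remove(wb.active)
    for name in SHEETS:
        wb.create_sheet(name)

    ws = wb["Summary"]
    rec = run.recommendation
    solvents = " / ".join(s for s in rec.triplet if s) if rec.support else "none"
    ratio_text = "; ".join(f"{k}: {v:.0f}%" for k, v in rec.median_ratios.items())
    rows = [
        ("software_version", run.version),
        ("seed", run.seed),
        ("learner", run.learner),
        ("winning_config", repr(run.config)),
        ("polymer", run.query.polymer),
        ("collector_type", run.query.collector_type),
        *[(p, float(getattr(run.query, p))) for p in PREDICTORS],
        ("predicted_diameter_nm", run.y_hat),
        ("bootstrap_B", run.predictive.B),
        ("solvent_recommendation", rec.message or solvents),
        ("solvent_median_ratios", ratio_text or "n/a"),
        ("recommendation_support", rec.support),
        ("recommendation_weight_w", rec.w),
    ]
    ws.append(["field", "value"])
    for row in rows:
        ws.append(list(row))

    ws = wb["Out_of_Range"]
    if run.ranges.all_in_range:
        ws.append(["all user-entered parameters are within the observed range"])
    _write_df(ws, run.ranges.table)

    _write_df(wb["CV_Predictions"], run.cv_table)

    ws = wb["Prediction_Distribution"]
    _write_df(ws, pd.DataFrame({"draw_nm": run.predictive.draws}))
    _embed(ws, _fig_distribution(run), "C2")
    _embed(ws, _fig_pred_obs(run), "C28")

    ws = wb["Metrics"]
    _write_df(ws, run.cv.per_fold_metrics)
    ws.append([])
    ws.append(["metric", "mean", "sd"])
    for metric, (mean, sd) in run.cv.summary.items():
        ws.append([metric, mean, sd])

    ws = wb["Coefficients"]
    if run.coefficients is not None:
        _write_df(ws, run.coefficients)
    else:
        ws.append([NO_COEF_MARKER])

    ws = wb["Variable_Importance"]
    _write_df(ws, run.importance.rename_axis("feature").reset_index())
    _embed(ws, _fig_importance(run), "D2")

    ws = wb["SHAP_Summary"]
    summary = run.attributions.mean_abs.rename("mean_abs_shap_nm")
    _write_df(ws, summary.rename_axis("feature").reset_index())
    ws.append([])
    ws.append(["baseline_nm", run.attributions.baseline])
    ws.append(["nsim", run.attributions.nsim])
    _embed(ws, _fig_shap(run), "D2")

    ws = wb["Correlation_Matrix"]
    _write_df(ws, run.correlations.rename_axis("variable").reset_index())
    _embed(ws, _fig_corr(run), "J2")

    wb.save(path)
    log.info("report written to %s", path)
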
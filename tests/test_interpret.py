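import numpy as np
import pandas as pd
import pytest

from fibredist.interpret import (
    correlation_matrix,
    response_surface,
    shap_values,
    variable_importance,
)
from fibredist.io import OUTCOME, PREDICTORS
from fibredist.learners import fit
from fibredist.preprocess import fit_recipe
from fibredist.report import PredictionPipeline


class _Linear:
    """Explicit linear predictor for closed-form oracles."""

    def __init__(self, beta, intercept=0.0):
        self.beta = np.asarray(beta, dtype=float)
        self.intercept = intercept

    def predict(self, X):
        return pd.DataFrame(X).to_numpy(dtype=float) @ self.beta + self.intercept


class _Constant:
    def predict(self, X):
        return np.full(len(pd.DataFrame(X)), 42.0)


class TestVariableImportance:
    def test_unused_feature_scores_zero(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.normal(size=40), "b": rng.normal(size=40)})
        y = np.where(X["a"] > 0, 10.0, -10.0)  # single split on a only
        model = fit("decision_tree", {"cp": 0.01}, X, y, seed=0)
        imp = variable_importance(model, X, y, seed=1)
        assert imp["b"] == pytest.approx(0.0, abs=1e-6)
        assert imp["a"] == 100.0

    def test_concentration_ranked_first_on_synthetic(self, small_ds):
        X = small_ds.df[PREDICTORS]
        y = small_ds.df[OUTCOME].to_numpy()
        recipe = fit_recipe(X)
        model = fit("random_forest", {"mtry": 2, "min_node_size": 5, "num_trees": 50},
                    recipe.transform(X), y, seed=0)
        imp = variable_importance(PredictionPipeline(recipe, model), X, y, seed=0)
        assert imp.index[0] == "concentration"

    def test_duplicated_features_share_importance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=60)
        X = pd.DataFrame({"u": x, "v": x, "w": rng.normal(size=60)})
        y = 5 * x + rng.normal(0, 0.1, 60)
        model = fit("linear", {}, X, y)
        imp = variable_importance(model, X, y, seed=3)
        assert abs(imp["u"] - imp["v"]) <= 0.1 * max(imp["u"], imp["v"])

    def test_degenerate_outcome_errors(self):
        X = pd.DataFrame({"a": np.arange(12.0)})
        with pytest.raises(ValueError, match="degenerate"):
            variable_importance(_Constant(), X, np.ones(12), seed=0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        y = X["a"].to_numpy() * 2 + rng.normal(0, 0.5, 30)
        model = fit("linear", {}, X, y)
        i1 = variable_importance(model, X, y, seed=7)
        i2 = variable_importance(model, X, y, seed=7)
        pd.testing.assert_series_equal(i1, i2)


class TestShap:
    def test_linear_closed_form(self):
        """MC Shapley -> beta_j * (x_j - mean background_j) for linear models."""
        rng = np.random.default_rng(5)
        beta = np.array([3.0, -2.0, 1.0])
        bg = pd.DataFrame(rng.normal(0, 1, size=(100, 3)), columns=list("abc"))
        inst = bg.iloc[:4]
        model = _Linear(beta, intercept=10.0)
        nsim = 500
        att = shap_values(model, inst, bg, nsim=nsim, seed=0)
        expected = (inst.to_numpy() - bg.mean().to_numpy()) * beta
        se = np.abs(beta) * bg.std(ddof=1).to_numpy() / np.sqrt(nsim)
        err = np.abs(att.shap.to_numpy() - expected)
        assert np.all(err < 3 * se + 1e-9)

    def test_constant_model_zero(self):
        rng = np.random.default_rng(6)
        bg = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        att = shap_values(_Constant(), bg.iloc[:3], bg, nsim=20, seed=0)
        assert np.allclose(att.shap.to_numpy(), 0.0)
        assert att.baseline == pytest.approx(42.0)

    def test_local_accuracy_linear(self):
        rng = np.random.default_rng(7)
        beta = np.array([2.0, 1.0])
        bg = pd.DataFrame(rng.normal(size=(80, 2)), columns=["a", "b"])
        inst = bg.iloc[:3]
        model = _Linear(beta, intercept=-5.0)
        nsim = 400
        att = shap_values(model, inst, bg, nsim=nsim, seed=1)
        preds = model.predict(inst)
        recon = att.shap.sum(axis=1).to_numpy() + att.baseline
        se_sum = np.std(model.predict(bg), ddof=1) / np.sqrt(nsim)
        assert np.all(np.abs(recon - preds) < 3 * se_sum + 1e-9)

    def test_mc_variance_shrinks_like_one_over_nsim(self):
        rng = np.random.default_rng(8)
        beta = np.array([4.0, -1.0])
        bg = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        inst = bg.iloc[[0]]
        model = _Linear(beta)
        nsims = [8, 32, 128]
        variances = []
        for nsim in nsims:
            vals = [
                shap_values(model, inst, bg, nsim=nsim, seed=s).shap.iloc[0, 0]
                for s in range(10)
            ]
            variances.append(np.var(vals, ddof=1))
        slope = np.polyfit(np.log(nsims), np.log(variances), 1)[0]
        assert -1.3 <= slope <= -0.7

    def test_background_too_small_errors(self):
        bg = pd.DataFrame({"a": [1.0]})
        with pytest.raises(ValueError, match="background"):
            shap_values(_Constant(), bg, bg, nsim=5)

    def test_top_features_ordering(self):
        rng = np.random.default_rng(9)
        beta = np.array([10.0, 1.0, 0.1])
        bg = pd.DataFrame(rng.normal(size=(60, 3)), columns=["big", "mid", "tiny"])
        att = shap_values(_Linear(beta), bg.iloc[:10], bg, nsim=100, seed=2)
        assert att.top_features(2) == ["big", "mid"]


class TestCorrelation:
    def test_perfect_and_diagonal(self, small_ds):
        mat = correlation_matrix(small_ds)
        assert np.allclose(np.diag(mat), 1.0)
        assert np.allclose(mat, mat.T, equal_nan=True)

    def test_hand_computed_inverse(self):
        df = pd.DataFrame({
            "concentration": [1.0, 2.0, 3.0],
            "diameter": [3.0, 2.0, 1.0],
        })
        mat = correlation_matrix(df)
        assert mat.loc["concentration", "diameter"] == pytest.approx(-1.0)

    def test_scaled_copy(self):
        df = pd.DataFrame({"voltage": [1.0, 2.0, 4.0]})
        df["diameter"] = 2 * df["voltage"]
        mat = correlation_matrix(df)
        assert mat.loc["voltage", "diameter"] == pytest.approx(1.0)


class TestResponseSurface:
    def test_constant_model_flat(self, small_ds):
        surf = response_surface(_Constant(), "concentration", "voltage", 5, small_ds)
        assert np.allclose(surf["predicted_diameter"], 42.0)
        assert len(surf) == 25

    def test_linear_model_straight_cross_sections(self, small_ds):
        beta = np.ones(len(PREDICTORS))
        model = _Linear(beta)
        surf = response_surface(model, "concentration", "voltage", 8, small_ds)
        grid = surf.pivot(index="concentration", columns="voltage",
                          values="predicted_diameter").to_numpy()
        second_diff_rows = np.diff(grid, n=2, axis=0)
        second_diff_cols = np.diff(grid, n=2, axis=1)
        assert np.max(np.abs(second_diff_rows)) < 1e-8
        assert np.max(np.abs(second_diff_cols)) < 1e-8

    def test_corners_match_direct_predict(self, small_ds):
        rng = np.random.default_rng(1)
        model = _Linear(rng.normal(size=len(PREDICTORS)))
        surf = response_surface(model, "concentration", "flow_rate", 4, small_ds)
        medians = small_ds.df[PREDICTORS].median()
        corner = surf.iloc[0]
        row = medians.copy()
        row["concentration"] = corner["concentration"]
        row["flow_rate"] = corner["flow_rate"]
        direct = model.predict(row.to_frame().T[PREDICTORS])[0]
        assert corner["predicted_diameter"] == pytest.approx(direct, abs=1e-12)

    def test_unknown_feature_errors(self, small_ds):
        with pytest.raises(ValueError, match="not a model predictor"):
            response_surface(_Constant(), "temperature", "voltage", 4, small_ds)
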
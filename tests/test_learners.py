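import numpy as np
import pytest

from fibredist.learners import (
    CP_GRID,
    LAMBDA_GRID,
    LEARNER_NAMES,
    fit,
    make_estimator,
    make_grid,
    predict,
    rbf_sigma_heuristic,
)
from fibredist.mars import MarsRegressor


class TestGrids:
    """The tuning grids are fixed deterministic sets."""

    def test_knn(self):
        assert make_grid("knn", 6, 100) == [{"k": k} for k in (3, 5, 7, 9, 11)]

    def test_mars(self):
        grid = make_grid("mars", 6, 100)
        assert len(grid) == 10
        assert {(g["degree"], g["nprune"]) for g in grid} == {
            (d, n) for d in (1, 2) for n in (5, 10, 15, 20, 25)
        }

    def test_random_forest(self):
        grid = make_grid("random_forest", 6, 100)
        assert len(grid) == 18
        assert all(g["num_trees"] == 500 for g in grid)
        assert {g["mtry"] for g in grid} == set(range(1, 7))
        assert {g["min_node_size"] for g in grid} == {1, 5, 10}

    def test_svm(self):
        assert [g["C"] for g in make_grid("svm_rbf", 6, 100)] == [0.25, 0.5, 1.0, 2.0, 4.0]

    def test_elastic_net(self):
        grid = make_grid("elastic_net", 6, 100)
        assert len(grid) == 5 * len(LAMBDA_GRID)
        assert sorted({g["alpha"] for g in grid}) == [0.0, 0.25, 0.5, 0.75, 1.0]
        assert LAMBDA_GRID[0] == pytest.approx(1e-4)
        assert LAMBDA_GRID[-1] == pytest.approx(1e1)

    def test_tree_and_linear(self):
        assert make_grid("linear", 6, 100) == [{}]
        cps = [g["cp"] for g in make_grid("decision_tree", 6, 100)]
        assert len(cps) == 10
        assert cps[0] == pytest.approx(1e-4)
        assert cps[-1] == pytest.approx(1e-1)
        assert np.allclose(np.diff(np.log10(CP_GRID)), np.diff(np.log10(CP_GRID))[0])

    def test_unknown_learner(self):
        with pytest.raises(ValueError, match="unknown learner"):
            make_grid("gbm", 6, 100)
        with pytest.raises(ValueError, match="unknown learner"):
            make_estimator("cubist")


class TestLinear:
    def test_exact_fit(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        model = fit("linear", {}, X, 2.0 * X[:, 0])
        assert model.coef_[0] == pytest.approx(2.0, abs=1e-9)
        assert model.intercept_ == pytest.approx(0.0, abs=1e-9)
        assert model.coefficients_table_["term"].tolist() == ["(intercept)", "x0"]

    def test_dot_product_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        model = fit("linear", {}, X, y)
        Xnew = rng.normal(size=(3, 3))
        oracle = Xnew @ model.coef_ + model.intercept_
        assert np.allclose(predict(model, Xnew), oracle, atol=1e-10)

    def test_singular_design_warns(self):
        X = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.warns(UserWarning, match="singular"):
            model = fit("linear", {}, X, np.array([1.0, 2.0, 3.0]))
        assert np.all(np.isfinite(predict(model, X)))


class TestKNN:
    def test_k1_nearest_self(self):
        X = np.array([[0.0], [1.0], [5.0]])
        y = np.array([10.0, 20.0, 30.0])
        model = fit("knn", {"k": 1}, X, y)
        assert predict(model, X).tolist() == y.tolist()

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(50, 4))
        y = rng.normal(size=50)
        Xq = rng.normal(size=(15, 4))
        model = fit("knn", {"k": 3}, X, y)
        got = predict(model, Xq)
        for i, q in enumerate(Xq):
            d = np.sqrt(((X - q) ** 2).sum(axis=1))
            nearest = np.argsort(d, kind="stable")[:3]
            assert got[i] == pytest.approx(y[nearest].mean(), abs=1e-12)

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match="at least"):
            fit("knn", {"k": 5}, np.zeros((3, 1)), np.zeros(3))


class TestOtherLearners:
    def test_rf_constant_outcome(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 3))
        model = fit("random_forest", {"mtry": 2, "min_node_size": 5, "num_trees": 25}, X,
                    np.full(30, 7.0), seed=0)
        assert np.allclose(predict(model, X), 7.0)

    def test_duplicate_rows_identical_predictions(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 2))
        y = rng.normal(size=40)
        Xq = np.vstack([X[:3], X[:3]])
        for name, config in [
            ("decision_tree", {"cp": 0.01}),
            ("svm_rbf", {"C": 1.0}),
            ("elastic_net", {"alpha": 0.5, "lam": 0.01}),
        ]:
            model = fit(name, config, X, y, seed=1)
            p = predict(model, Xq)
            assert np.array_equal(p[:3], p[3:])

    def test_empty_prediction(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        model = fit("knn", {"k": 3}, X, X[:, 0])
        assert predict(model, np.empty((0, 2))).shape == (0,)

    def test_refit_reproducibility(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(60, 3))
        y = rng.normal(size=60)
        for name, config, tol in [
            ("random_forest", {"mtry": 2, "min_node_size": 5, "num_trees": 50}, 0.0),
            ("decision_tree", {"cp": 0.001}, 0.0),
            ("knn", {"k": 3}, 0.0),
            ("elastic_net", {"alpha": 0.5, "lam": 0.01}, 1e-8),
        ]:
            p1 = predict(fit(name, config, X, y, seed=4), X)
            p2 = predict(fit(name, config, X, y, seed=4), X)
            assert np.allclose(p1, p2, atol=tol)

    def test_elastic_net_extremes(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 3))
        y = 3 * X[:, 0] + rng.normal(0, 0.1, 50)
        ridge = fit("elastic_net", {"alpha": 0.0, "lam": 1e-4}, X, y)
        lasso_strong = fit("elastic_net", {"alpha": 1.0, "lam": 10.0}, X, y)
        assert ridge.coef_[0] == pytest.approx(3.0, abs=0.1)
        assert np.allclose(lasso_strong.coef_, 0.0)  # heavy L1 kills all effects


class TestSigmaHeuristic:
    def test_two_point_median_rule(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])  # distance 5
        assert rbf_sigma_heuristic(X) == pytest.approx(1.0 / 25.0)

    def test_scaling_homogeneity(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 4))
        s1 = rbf_sigma_heuristic(X, seed=0)
        s2 = rbf_sigma_heuristic(3.0 * X, seed=0)
        assert s2 == pytest.approx(s1 / 9.0)

    def test_identical_rows_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            rbf_sigma_heuristic(np.ones((5, 2)))


class TestMars:
    def test_single_hinge_exact_recovery(self):
        rng = np.random.default_rng(4)
        x = np.sort(rng.uniform(-2, 2, 60))
        knot = x[25]  # knot at an observed value
        y = 2.5 * np.maximum(0.0, x - knot) - 0.5
        model = MarsRegressor(degree=1, nprune=15).fit(x.reshape(-1, 1), y)
        rmse = np.sqrt(np.mean((model.predict(x.reshape(-1, 1)) - y) ** 2))
        assert rmse < 1e-6

    def test_interaction_needs_degree_two(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(-1, 1, size=(120, 2))
        y = np.maximum(0, X[:, 0]) * np.maximum(0, X[:, 1])
        additive = MarsRegressor(degree=1, nprune=15).fit(X, y)
        interact = MarsRegressor(degree=2, nprune=15).fit(X, y)
        rmse = lambda m: np.sqrt(np.mean((m.predict(X) - y) ** 2))
        assert rmse(interact) < rmse(additive)

    def test_nprune_caps_terms(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(-1, 1, size=(80, 3))
        y = np.sin(3 * X[:, 0]) + X[:, 1] ** 2
        model = MarsRegressor(degree=1, nprune=5).fit(X, y)
        assert len(model.terms_) <= 5


def test_all_learners_fit_predict(small_ds):
    """Uniform contract: every registry learner fits and predicts finitely."""
    from fibredist.io import OUTCOME, PREDICTORS
    from fibredist.preprocess import fit_recipe

    X = small_ds.df[PREDICTORS]
    y = small_ds.df[OUTCOME].to_numpy()
    recipe = fit_recipe(X)
    Z = recipe.transform(X)
    configs = {
        "linear": {},
        "elastic_net": {"alpha": 0.5, "lam": 0.01},
        "decision_tree": {"cp": 0.01},
        "mars": {"degree": 1, "nprune": 10},
        "knn": {"k": 3},
        "random_forest": {"mtry": 2, "min_node_size": 5, "num_trees": 25},
        "svm_rbf": {"C": 1.0},
    }
    assert set(configs) == set(LEARNER_NAMES)
    for name, config in configs.items():
        model = fit(name, config, Z, y, seed=0)
        preds = predict(model, Z)
        assert preds.shape == (len(y),)
        has_table = hasattr(model, "coefficients_table_")
        assert has_table == (name in ("linear", "elastic_net"))
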
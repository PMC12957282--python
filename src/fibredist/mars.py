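"""Multivariate adaptive regression splines (MARS).

Forward stepwise selection of mirrored hinge-basis pairs followed by
backward pruning scored by generalised cross-validation (GCV).  A basis
function is a product of hinges h(x) = max(0, +/-(x_v - t)) with knots t
placed at observed data values; ``degree`` bounds the number of hinge
factors per term and ``nprune`` caps the number of terms (including the
intercept) retained after pruning.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

# A term is a tuple of factors; each factor is (var_index, sign, knot) with
# sign +1 for max(0, x - t) and -1 for max(0, t - x).  The intercept is ().


def _term_column(X: np.ndarray, term: tuple) -> np.ndarray:
    col = np.ones(X.shape[0])
    for var, sign, knot in term:
        col = col * np.maximum(0.0, sign * (X[:, var] - knot))
    return col


def _basis_matrix(X: np.ndarray, terms: list[tuple]) -> np.ndarray:
    return np.column_stack([_term_column(X, t) for t in terms])


def _gcv(rss: float, n: int, n_terms: int, penalty: float) -> float:
    eff = n_terms + penalty * (n_terms - 1) / 2.0
    if eff >= n:
        return np.inf
    return (rss / n) / (1.0 - eff / n) ** 2


class MarsRegressor(RegressorMixin, BaseEstimator):
    """Piecewise-linear hinge-basis regression with GCV pruning.

    Parameters
    ----------
    degree : int
        Maximum number of hinge factors multiplied in one basis term
        (1 = additive, 2 = pairwise interactions).
    nprune : int or None
        Maximum number of terms (intercept included) kept after backward
        pruning; the pruned model is the GCV-best subset of that size or
        smaller.
    max_terms : int or None
        Forward-pass cap on terms; defaults to max(21, 2*nprune + 1).
    max_knots : int
        Cap on candidate knots per (parent, variable); candidates are the
        observed values, evenly thinned when more numerous.
    """

    def __init__(self, degree: int = 1, nprune: int | None = None,
                 max_terms: int | None = None, max_knots: int = 64):
        self.degree = degree
        self.nprune = nprune
        self.max_terms = max_terms
        self.max_knots = max_knots

    # -- forward pass -----------------------------------------------------
    def _candidate_knots(self, x_active: np.ndarray) -> np.ndarray:
        values = np.unique(x_active)
        if len(values) > self.max_knots:
            idx = np.linspace(0, len(values) - 1, self.max_knots).round().astype(int)
            values = values[np.unique(idx)]
        return values

    def _forward(self, X: np.ndarray, y: np.ndarray, max_terms: int) -> list[tuple]:
        n, p = X.shape
        terms: list[tuple] = [()]
        B = np.ones((n, 1))
        while B.shape[1] + 2 <= max_terms:
            Q, _ = np.linalg.qr(B)
            resid = y - Q @ (Q.T @ y)
            rss_now = float(resid @ resid)
            if rss_now <= 1e-12 * max(1.0, float(y @ y)):
                break
            best = None  # (rss, parent_idx, var, knot)
            for parent_idx, parent in enumerate(terms):
                if len(parent) >= self.degree:
                    continue
                used_vars = {v for v, _, _ in parent}
                parent_col = B[:, parent_idx]
                active = parent_col > 0
                if active.sum() < 2:
                    continue
                for var in range(p):
                    if var in used_vars:
                        continue
                    knots = self._candidate_knots(X[active, var])
                    if len(knots) < 2:
                        continue
                    xv = X[:, var]
                    for knot in knots:
                        c_pos = parent_col * np.maximum(0.0, xv - knot)
                        c_neg = parent_col * np.maximum(0.0, knot - xv)
                        C = np.column_stack([c_pos, c_neg])
                        C_perp = C - Q @ (Q.T @ C)
                        G = C_perp.T @ C_perp
                        b = C_perp.T @ resid
                        try:
                            a = np.linalg.solve(G + 1e-10 * np.eye(2) * max(G.max(), 1.0), b)
                        except np.linalg.LinAlgError:
                            continue
                        rss = rss_now - float(b @ a)
                        if best is None or rss < best[0] - 1e-12:
                            best = (rss, parent_idx, var, knot)
            if best is None:
                break
            rss, parent_idx, var, knot = best
            if rss_now - rss <= 1e-10 * max(rss_now, 1e-30):
                break
            parent = terms[parent_idx]
            t_pos = parent + ((var, 1, float(knot)),)
            t_neg = parent + ((var, -1, float(knot)),)
            terms.extend([t_pos, t_neg])
            B = np.column_stack([B, _term_column(X, t_pos), _term_column(X, t_neg)])
        return terms

    # -- backward pass ----------------------------------------------------
    def _backward(self, X: np.ndarray, y: np.ndarray, terms: list[tuple]) -> list[tuple]:
        n = len(y)
        penalty = 2.0 if self.degree == 1 else 3.0
        current = list(terms)

        def rss_of(subset: list[tuple]) -> float:
            B = _basis_matrix(X, subset)
            coef, _, _, _ = np.linalg.lstsq(B, y, rcond=None)
            r = y - B @ coef
            return float(r @ r)

        best_subset = list(current)
        best_gcv = _gcv(rss_of(current), n, len(current), penalty)
        cap = self.nprune if self.nprune is not None else len(terms)
        if len(current) <= cap and best_gcv < np.inf:
            sized_best = {len(current): (best_gcv, list(current))}
        else:
            sized_best = {}
        while len(current) > 1:
            candidates = []
            for i, term in enumerate(current):
                if term == ():
                    continue
                subset = current[:i] + current[i + 1:]
                candidates.append((rss_of(subset), i, subset))
            if not candidates:
                break
            rss, _, subset = min(candidates, key=lambda c: (c[0], c[1]))
            current = subset
            g = _gcv(rss, n, len(current), penalty)
            size = len(current)
            if size not in sized_best or g < sized_best[size][0]:
                sized_best[size] = (g, list(current))
        eligible = {s: v for s, v in sized_best.items() if s <= cap}
        if not eligible:
            return [()]
        _, chosen = min(eligible.values(), key=lambda v: v[0])
        return chosen

    # -- sklearn API ------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be 2-D with one outcome per row")
        n, p = X.shape
        cap = self.nprune if self.nprune is not None else 21
        max_terms = self.max_terms if self.max_terms is not None else max(21, 2 * cap + 1)
        max_terms = min(max_terms, n)
        terms = self._forward(X, y, max_terms)
        terms = self._backward(X, y, terms)
        B = _basis_matrix(X, terms)
        coef, _, _, _ = np.linalg.lstsq(B, y, rcond=None)
        self.terms_ = terms
        self.coef_ = coef
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "terms_")
        X = np.asarray(X, dtype=float)
        if X.shape[0] == 0:
            return np.empty(0)
        return _basis_matrix(X, self.terms_) @ self.coef_
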
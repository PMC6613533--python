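"""Penalized B-spline (P-spline) generalized additive model of mass loss
versus time.

The smooth is a cubic B-spline basis on equally spaced knots (L domain
segments -> L + degree basis functions), with a second-order difference
penalty on the spline coefficients.  The fit minimises

    ||y - X beta||^2 + lambda * beta' D2' D2 beta

and the smoothing parameter lambda is chosen by minimising the
generalized cross-validation score

    GCV(lambda) = n * SSE / (n - tr(H))^2

over a logarithmic grid.  Because the penalty nullspace contains all
straight lines, an exactly linear signal is reproduced exactly at any
lambda; the smooth only shrinks curvature.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline
from sklearn.base import BaseEstimator, RegressorMixin

from ._utils import check
from .kinetics import r_squared

__all__ = ["PSplineGAM", "fit_gam"]


def _bspline_design(x, xmin, xmax, n_segments, degree):
    """Design matrix of an equally spaced B-spline basis covering
    [xmin, xmax] with ``n_segments`` intervals (Eilers–Marx layout:
    knots extend ``degree`` steps beyond each boundary, giving
    ``n_segments + degree`` basis functions and equally spaced Greville
    points, so polynomial reproduction up to the penalty order is exact).
    """
    h = (xmax - xmin) / n_segments
    knots = xmin + h * np.arange(-degree, n_segments + degree + 1)
    X = BSpline.design_matrix(np.clip(x, xmin, xmax), knots, degree,
                              extrapolate=False).toarray()
    return X, knots


class PSplineGAM(RegressorMixin, BaseEstimator):
    """Penalized-spline smoother with GCV-selected smoothing.

    Parameters
    ----------
    n_knots : int
        Number of knot intervals L over the data range (default 10); the
        basis has ``L + degree`` functions.
    degree : int
        Spline degree (default 3, cubic).
    penalty_order : int
        Order of the coefficient difference penalty (default 2).
    lambda_grid : array-like, optional
        Candidate smoothing parameters; default 50 log-spaced points in
        [1e-6, 1e6].

    Attributes
    ----------
    coef_ : (L + degree,) spline coefficients at the selected lambda.
    lambda_ : selected smoothing parameter.
    gcv_path_ : DataFrame-like dict of the lambda grid and GCV scores.
    edof_ : effective degrees of freedom tr(H) at the selected lambda.
    fitted_values_, r_squared_ : training-fit diagnostics.
    """

    def __init__(self, n_knots: int = 10, degree: int = 3,
                 penalty_order: int = 2, lambda_grid=None):
        self.n_knots = n_knots
        self.degree = degree
        self.penalty_order = penalty_order
        self.lambda_grid = lambda_grid

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        check(x.size == y.size, "X and y must have the same length")
        check(np.all(np.isfinite(x)) and np.all(np.isfinite(y)),
              "inputs must be finite")
        check(self.n_knots >= 2, "n_knots must be >= 2")
        check(1 <= self.penalty_order < self.n_knots + self.degree,
              "invalid penalty order")
        n_distinct = np.unique(x).size
        check(n_distinct >= self.penalty_order + 1,
              "too few distinct x values; reduce n_knots or penalty order")
        xmin, xmax = float(x.min()), float(x.max())
        check(xmax > xmin, "x must span a nonzero range")

        B, knots = _bspline_design(x, xmin, xmax, self.n_knots, self.degree)
        nb = B.shape[1]
        D = np.diff(np.eye(nb), n=self.penalty_order, axis=0)
        P = D.T @ D
        BtB = B.T @ B
        Bty = B.T @ y
        n = x.size
        grid = (np.asarray(self.lambda_grid, dtype=float)
                if self.lambda_grid is not None
                else np.logspace(-6, 6, 50))

        best = None
        gcv_scores = []
        for lam in grid:
            A = BtB + lam * P
            try:
                beta = np.linalg.solve(A, Bty)
                A_inv_BtB = np.linalg.solve(A, BtB)
            except np.linalg.LinAlgError:
                beta = np.linalg.pinv(A) @ Bty
                A_inv_BtB = np.linalg.pinv(A) @ BtB
            fitted = B @ beta
            sse = float(np.sum((y - fitted) ** 2))
            edof = float(np.trace(A_inv_BtB))
            denom = (n - edof) ** 2
            gcv = n * sse / denom if denom > 1e-12 else np.inf
            gcv_scores.append(gcv)
            if best is None or gcv < best[0]:
                best = (gcv, lam, beta, fitted, edof)

        _, lam, beta, fitted, edof = best
        self.coef_ = beta
        self.knots_ = knots
        self.x_range_ = (xmin, xmax)
        self.lambda_ = float(lam)
        self.gcv_path_ = {"lambda": grid, "gcv": np.asarray(gcv_scores)}
        self.edof_ = edof
        self.fitted_values_ = fitted
        self.r_squared_ = r_squared(y, fitted) if np.var(y) > 0 else 1.0
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        """Evaluate the smooth; inputs outside the training range are
        clamped to the boundary (no spline extrapolation)."""
        x = np.asarray(X, dtype=float).reshape(-1)
        B, _ = _bspline_design(x, *self.x_range_, self.n_knots, self.degree)
        return B @ self.coef_


def fit_gam(x, y, n_knots: int = 10, degree: int = 3,
            lambda_grid=None) -> PSplineGAM:
    """Fit mass loss (or any response) on time with a P-spline GAM."""
    return PSplineGAM(n_knots=n_knots, degree=degree,
                      lambda_grid=lambda_grid).fit(x, y)
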
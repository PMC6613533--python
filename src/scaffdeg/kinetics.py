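"""Degradation kinetics: logistic-mixture regression with global
initialisation, asymptotic inference and residual-bootstrap intervals.

The mass-loss trajectory of a collagen scaffold colonised by
differentiating cells superimposes several sigmoid degradation processes
(e.g. an early hydrolytic step and a later cell-driven step).  The model is
a sum of ``k`` logistic components

    y(t) = sum_i  A_i / (1 + exp((mu_i - t) / scal_i))

where ``A_i`` is the asymptotic mass-loss contribution (%), ``mu_i`` the
inflection time (days) and ``scal_i`` the time scale (days) of component
``i``.  Fitting combines a seeded differential-evolution global search with
a derivative-based least-squares refinement, which is robust to the multiple
local minima of overlapping-component mixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from ._utils import ValidationError, check, rng_from_seed, spawn_seeds

__all__ = [
    "logistic",
    "gompertz",
    "mixture_predict",
    "r_squared",
    "LogisticMixtureRegressor",
    "BootstrapCI",
    "bootstrap_parameters",
    "fit_mixture",
]


def logistic(t, A: float, mu: float, scal: float):
    """One logistic sigmoid: ``A / (1 + exp((mu - t) / scal))``.

    Strictly increasing in ``t`` for ``A > 0``; equals ``A/2`` at ``t = mu``.
    """
    check(scal > 0, "scal must be > 0")
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore"):  # exp overflow -> inf -> y = 0, exact
        return A / (1.0 + np.exp((mu - t) / scal))


def gompertz(t, A: float, mu_rate: float, lag: float):
    """Gompertz growth curve ``A exp[-exp((mu_rate*e/A)(lag - t) + 1)]``.

    ``A`` is the asymptote, ``mu_rate`` the maximum slope and ``lag`` the
    delay before exponential growth; ``y(lag) = A exp(-e)``.
    """
    check(A > 0, "A must be > 0")
    t = np.asarray(t, dtype=float)
    return A * np.exp(-np.exp((mu_rate * np.e / A) * (lag - t) + 1.0))


def mixture_predict(t, theta):
    """Evaluate a k-component logistic mixture at times ``t``.

    ``theta`` is the flat vector (A_1, mu_1, scal_1, ..., A_k, mu_k,
    scal_k).  Monotone nondecreasing in ``t`` when all A_i, scal_i > 0;
    the t -> inf limit is sum(A_i).
    """
    theta = np.asarray(theta, dtype=float)
    check(theta.size >= 3 and theta.size % 3 == 0,
          f"theta must have 3k entries, got {theta.size}")
    comps = theta.reshape(-1, 3)
    check(np.all(comps[:, 2] > 0), "all scal_i must be > 0")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t, dtype=float)
    with np.errstate(over="ignore"):
        for A, mu, scal in comps:
            out = out + A / (1.0 + np.exp((mu - t) / scal))
    return out


def r_squared(y, y_hat) -> float:
    """Coefficient of determination ``1 - SSE/SST`` (Kvålseth's general
    definition): valid for nonlinear fits, at most 1, may be negative."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    check(y.size >= 2, "need at least 2 observations")
    check(y.shape == y_hat.shape, "y and y_hat must have the same shape")
    sst = float(np.sum((y - y.mean()) ** 2))
    check(sst > 0, "constant response: R^2 undefined")
    sse = float(np.sum((y - y_hat) ** 2))
    return 1.0 - sse / sst


def _sort_components(theta: np.ndarray) -> np.ndarray:
    comps = theta.reshape(-1, 3)
    return comps[np.argsort(comps[:, 1])].ravel()


class LogisticMixtureRegressor(RegressorMixin, BaseEstimator):
    """Sum-of-logistics regression of mass loss (%) on time (days).

    Parameters
    ----------
    n_components : int
        Number of logistic components ``k``.
    bounds : array-like of shape (3k, 2), optional
        Box constraints on the flat parameter vector.  Default per
        component: A in (0, 100] (a percentage), mu in [min(t), max(t)]
        and scal in [0.1, 20] days — the physical ranges of a percent
        mass-loss process over a 44-day experiment.
    de_popsize, de_maxiter : int
        Differential-evolution population multiplier (individuals per
        parameter) and generation budget for the global search.
    random_state : int, optional
        Seeds the global search; the refinement is deterministic.

    Attributes
    ----------
    theta_ : ndarray of shape (3k,)
        Fitted parameters, components sorted by inflection time.
    components_ : ndarray of shape (k, 3)
        ``theta_`` reshaped to (A, mu, scal) rows.
    r_squared_ : float
    std_errors_, t_values_, p_values_ : ndarray of shape (3k,)
        Asymptotic (linearised least-squares) inference.
    residuals_ : ndarray of shape (n,)
    converged_ : bool
    """

    _parameter_names_template = ("A", "mu", "scal")

    def __init__(self, n_components: int = 2, bounds=None,
                 de_popsize: int = 10, de_maxiter: int = 300,
                 random_state: int | None = None):
        self.n_components = n_components
        self.bounds = bounds
        self.de_popsize = de_popsize
        self.de_maxiter = de_maxiter
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _default_bounds(self, t: np.ndarray) -> np.ndarray:
        lo_hi = [(1e-6, 100.0), (float(t.min()), float(t.max())), (0.1, 20.0)]
        return np.asarray(lo_hi * self.n_components, dtype=float)

    def _validate_xy(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        check(t.size == y.size, "X and y must have the same length")
        check(np.all(np.isfinite(t)) and np.all(np.isfinite(y)),
              "inputs must be finite")
        k = self.n_components
        check(k >= 1, "n_components must be >= 1")
        check(t.size >= 3 * k + 1,
              f"need at least {3 * k + 1} observations for k={k}")
        return t, y

    def fit(self, X, y):
        """Fit by seeded differential evolution followed by bounded
        least-squares refinement; components are sorted by mu."""
        t, y = self._validate_xy(X, y)
        k = self.n_components
        bounds = (np.asarray(self.bounds, dtype=float) if self.bounds is not None
                  else self._default_bounds(t))
        check(bounds.shape == (3 * k, 2), "bounds must have shape (3k, 2)")

        def sse(theta):
            return float(np.sum((y - mixture_predict(t, theta)) ** 2))

        de = optimize.differential_evolution(
            sse, bounds=bounds, seed=self.random_state,
            popsize=self.de_popsize, maxiter=self.de_maxiter,
            tol=1e-10, polish=False)
        refined = optimize.least_squares(
            lambda th: y - mixture_predict(t, th), de.x,
            bounds=(bounds[:, 0], bounds[:, 1]), method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        if not (de.success or refined.cost <= de.fun):
            raise RuntimeError(
                "mixture fit did not converge; best candidate: "
                f"theta={de.x}, SSE={de.fun:.4g}")

        theta = _sort_components(refined.x)
        # refresh jacobian at the sorted parameters (column order changes)
        final = optimize.least_squares(
            lambda th: y - mixture_predict(t, th), theta,
            bounds=(bounds[:, 0], bounds[:, 1]), method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        theta = _sort_components(final.x)

        n, p = t.size, 3 * k
        resid = y - mixture_predict(t, theta)
        dof = max(n - p, 1)
        s2 = float(resid @ resid) / dof
        J = final.jac
        JtJ = J.T @ J
        try:
            cov = s2 * np.linalg.inv(JtJ)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            cov = np.full((p, p), np.nan)
            se = np.full(p, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = theta / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)

        self.n_features_in_ = 1
        self.theta_ = theta
        self.components_ = theta.reshape(-1, 3)
        self.parameter_names_ = [f"{nm}_{i + 1}" for i in range(k)
                                 for nm in self._parameter_names_template]
        self.residuals_ = resid
        self.r_squared_ = r_squared(y, mixture_predict(t, theta))
        self.cov_ = cov
        self.std_errors_ = se
        self.t_values_ = tvals
        self.p_values_ = pvals
        self.converged_ = True
        self.bounds_ = bounds
        self._t_fit, self._y_fit = t, y
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).reshape(-1)
        return mixture_predict(t, self.theta_)

    def summary(self):
        """Parameter table (estimate, SE, t, p) as a pandas DataFrame."""
        import pandas as pd

        return pd.DataFrame({
            "estimate": self.theta_,
            "std_error": self.std_errors_,
            "t_value": self.t_values_,
            "p_value": self.p_values_,
        }, index=self.parameter_names_)


@dataclass(frozen=True)
class BootstrapCI:
    """Percentile bootstrap confidence bounds per parameter."""

    parameter_names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray
    level: float
    n_resamples: int
    n_failed: int
    seed: int | None


def bootstrap_parameters(model: LogisticMixtureRegressor, X=None, y=None,
                         B: int = 1000, level: float = 0.95,
                         seed: int | None = None,
                         max_failed_frac: float = 0.2) -> BootstrapCI:
    """Residual-bootstrap percentile intervals for a fitted mixture.

    Mean-centred residuals are resampled with replacement, added back to
    the fitted curve, and the model is refitted by bounded least squares
    warm-started from the point estimate (the global search is skipped —
    the resampled problems are small perturbations of the original).
    Refits that fail to converge are dropped and counted; more than
    ``max_failed_frac`` failures raises.
    """
    check(hasattr(model, "theta_"), "model must be fitted first")
    t = model._t_fit if X is None else np.asarray(X, float).reshape(-1)
    y = model._y_fit if y is None else np.asarray(y, float).reshape(-1)
    fitted = mixture_predict(t, model.theta_)
    resid = y - fitted
    resid = resid - resid.mean()
    rng = rng_from_seed(seed)
    bounds = (model.bounds_[:, 0], model.bounds_[:, 1])

    draws = []
    n_failed = 0
    for _ in range(B):
        y_b = fitted + rng.choice(resid, size=resid.size, replace=True)
        try:
            res = optimize.least_squares(
                lambda th: y_b - mixture_predict(t, th), model.theta_,
                bounds=bounds, method="trf", xtol=1e-10, ftol=1e-10)
            if not np.all(np.isfinite(res.x)):
                raise RuntimeError("non-finite refit")
            draws.append(_sort_components(res.x))
        except Exception:
            n_failed += 1
    if n_failed > max_failed_frac * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap refits failed (> {max_failed_frac:.0%})")
    draws = np.asarray(draws)
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(draws, alpha, axis=0)
    upper = np.quantile(draws, 1.0 - alpha, axis=0)
    return BootstrapCI(tuple(model.parameter_names_), lower, upper,
                       level, B, n_failed, seed)


def fit_mixture(records, k: int = 2, bounds=None,
                seed: int | None = None) -> LogisticMixtureRegressor:
    """Fit a k-component logistic mixture to mass-loss records.

    ``records`` is a DataFrame with columns ``time_days`` and
    ``mass_loss_pct`` (as produced by :func:`scaffdeg.synthetic.simulate_mass_loss`)
    or a ``(t, y)`` pair of arrays.
    """
    if hasattr(records, "columns"):
        t = records["time_days"].to_numpy(float)
        y = records["mass_loss_pct"].to_numpy(float)
    else:
        t, y = records
    return LogisticMixtureRegressor(
        n_components=k, bounds=bounds, random_state=seed).fit(t, y)
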
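"""Linear mass-loss models on log-transformed image features.

Collagen mass loss (%) is modelled by ordinary least squares on the
natural logarithms of per-image shape features (mean extracellular-matrix
object area, mean circularity, grayscale-histogram mode), optionally with
experimental-group dummy variables (CCO — cells plus osteogenic medium —
is the reference level).  The module also provides the LMG decomposition
of R^2 (incremental R^2 averaged over all predictor orderings) and seeded
k-fold predictive validation.
"""

from __future__ import annotations

from itertools import combinations, permutations
from math import factorial

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from ._utils import ValidationError, check, rng_from_seed
from .kinetics import r_squared

__all__ = [
    "MassLossLinearModel",
    "fit_linear",
    "relative_importance_lmg",
    "kfold_predictions",
]


class MassLossLinearModel(RegressorMixin, BaseEstimator):
    """OLS regression of a response on logged features and group dummies.

    Parameters
    ----------
    response : str
        Response column (default ``mass_loss_pct``).
    log_features : tuple of str
        Columns entered as natural logs; must be strictly positive.
    linear_features : tuple of str
        Columns entered untransformed.
    group_col : str or None
        Categorical column expanded into 0/1 dummies with ``reference``
        as the omitted reference level.
    reference : str
        Reference group level (default ``"CCO"``).

    Attributes
    ----------
    params_, bse_, tvalues_, pvalues_ : pandas Series indexed by term.
    r_squared_ : Kvålseth coefficient of determination.
    design_columns_ : tuple of design-matrix columns (without intercept).
    predictor_groups_ : mapping predictor-name -> design columns, with all
        group dummies collapsed into one predictor (used by the LMG
        decomposition).
    """

    def __init__(self, response: str = "mass_loss_pct",
                 log_features: tuple = ("mean_area_um2",),
                 linear_features: tuple = (),
                 group_col: str | None = None,
                 reference: str = "CCO"):
        self.response = response
        self.log_features = log_features
        self.linear_features = linear_features
        self.group_col = group_col
        self.reference = reference

    # ------------------------------------------------------------------
    def _design(self, table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
        cols = {}
        groups: dict[str, list[str]] = {}
        if self.group_col is not None:
            check(self.group_col in table, f"missing column {self.group_col}")
            levels = [lv for lv in pd.unique(table[self.group_col])
                      if lv != self.reference]
            dummy_names = []
            for lv in sorted(map(str, levels)):
                name = str(lv)
                cols[name] = (table[self.group_col].astype(str) == name).astype(float)
                dummy_names.append(name)
            if dummy_names:
                groups[self.group_col] = dummy_names
        for col in self.log_features:
            check(col in table, f"missing column {col}")
            vals = table[col].to_numpy(dtype=float)
            bad = np.flatnonzero(~(vals > 0))
            if bad.size:
                raise ValidationError(
                    f"column {col} must be strictly positive for the log "
                    f"transform; offending rows: {bad[:10].tolist()}")
            name = f"ln({col})"
            cols[name] = np.log(vals)
            groups[name] = [name]
        for col in self.linear_features:
            check(col in table, f"missing column {col}")
            cols[col] = table[col].to_numpy(dtype=float)
            groups[col] = [col]
        X = pd.DataFrame(cols, index=table.index)
        check(X.shape[1] >= 1, "model has no predictors")
        return X, groups

    def fit(self, table: pd.DataFrame, y=None):
        """Fit by OLS.  ``y`` defaults to ``table[self.response]``."""
        X, groups = self._design(table)
        yv = (np.asarray(y, dtype=float) if y is not None
              else table[self.response].to_numpy(dtype=float))
        check(yv.size == len(X), "response length mismatch")
        check(yv.size > X.shape[1] + 1,
              "need more observations than coefficients")
        design = sm.add_constant(X, has_constant="add")
        rank = np.linalg.matrix_rank(design.to_numpy())
        if rank < design.shape[1]:
            raise ValidationError(
                "rank-deficient design (collinear predictors among "
                f"{list(X.columns)})")
        res = sm.OLS(yv, design).fit()
        self.model_ = res
        self.params_ = res.params.rename({"const": "intercept"})
        self.bse_ = res.bse.rename({"const": "intercept"})
        self.tvalues_ = res.tvalues.rename({"const": "intercept"})
        self.pvalues_ = res.pvalues.rename({"const": "intercept"})
        self.r_squared_ = r_squared(yv, res.fittedvalues)
        self.design_columns_ = tuple(X.columns)
        self.predictor_groups_ = groups
        self._design_cache = (X.to_numpy(), yv)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, table: pd.DataFrame):
        X, _ = self._design(table)
        check(tuple(X.columns) == self.design_columns_,
              "table columns do not match the fitted design")
        design = sm.add_constant(X, has_constant="add")
        return np.asarray(self.model_.predict(design))

    def summary(self) -> pd.DataFrame:
        """Coefficient table (estimate, SE, t, p)."""
        return pd.DataFrame({
            "estimate": self.params_,
            "std_error": self.bse_,
            "t_value": self.tvalues_,
            "p_value": self.pvalues_,
        })


def fit_linear(table: pd.DataFrame, response: str = "mass_loss_pct",
               log_features=("mean_area_um2",), linear_features=(),
               group_col=None, reference="CCO") -> MassLossLinearModel:
    """Convenience wrapper over :class:`MassLossLinearModel`."""
    return MassLossLinearModel(
        response=response, log_features=tuple(log_features),
        linear_features=tuple(linear_features), group_col=group_col,
        reference=reference).fit(table)


def _subset_r2(Xfull: np.ndarray, y: np.ndarray, cols: tuple[int, ...],
               cache: dict) -> float:
    if cols in cache:
        return cache[cols]
    n = y.size
    if cols:
        design = np.column_stack([np.ones(n), Xfull[:, list(cols)]])
    else:
        design = np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    r2 = r_squared(y, design @ beta)
    cache[cols] = r2
    return r2


def relative_importance_lmg(model: MassLossLinearModel,
                            by_ordering: bool = False) -> pd.Series:
    """LMG relative-importance decomposition of the fitted model's R^2.

    Each predictor's share is its incremental R^2 averaged over all p!
    orderings of the predictors; the shares sum to the full-model R^2.
    Group dummies enter and leave the model together as one predictor.
    With ``by_ordering=True`` the orderings are enumerated explicitly
    (identical result, exponentially slower — kept for verification);
    otherwise subsets are enumerated and combinatorially weighted.
    Limited to p <= 8 predictors (exact enumeration).
    """
    check(hasattr(model, "predictor_groups_"), "model must be fitted first")
    groups = model.predictor_groups_
    names = list(groups)
    p = len(names)
    check(p >= 1, "no predictors")
    if p > 8:
        raise ValidationError(
            "LMG by exact enumeration supports at most 8 predictors; "
            "sampling of orderings is not implemented")
    Xfull, y = model._design_cache
    col_idx = {c: i for i, c in enumerate(model.design_columns_)}
    group_cols = {g: tuple(col_idx[c] for c in cols)
                  for g, cols in groups.items()}
    cache: dict = {}

    def r2_of(group_set) -> float:
        cols = tuple(sorted(c for g in group_set for c in group_cols[g]))
        return _subset_r2(Xfull, y, cols, cache)

    shares = dict.fromkeys(names, 0.0)
    if by_ordering:
        n_ord = factorial(p)
        for order in permutations(names):
            seen: list = []
            prev = r2_of(seen)
            for g in order:
                seen.append(g)
                cur = r2_of(seen)
                shares[g] += (cur - prev) / n_ord
                prev = cur
    else:
        for g in names:
            others = [o for o in names if o != g]
            for size in range(p):
                w = factorial(size) * factorial(p - size - 1) / factorial(p)
                for sub in combinations(others, size):
                    shares[g] += w * (r2_of(list(sub) + [g]) - r2_of(list(sub)))
    return pd.Series(shares, name="lmg_share")


def kfold_predictions(model: MassLossLinearModel, table: pd.DataFrame,
                      k: int = 3, seed: int | None = None) -> pd.DataFrame:
    """Seeded k-fold out-of-sample predictions.

    Rows are randomly assigned to ``k`` folds; for each fold the model is
    refitted on the remaining rows and predicts the held-out fold.
    Returns per-row (observed, predicted, fold) aligned with ``table``.
    """
    n = len(table)
    check(n >= k >= 2, "need 2 <= k <= n rows")
    rng = rng_from_seed(seed)
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for f, idx in enumerate(np.array_split(order, k)):
        folds[idx] = f
    observed = table[model.response].to_numpy(dtype=float)
    predicted = np.full(n, np.nan)
    from sklearn.base import clone

    for f in range(k):
        test = folds == f
        sub = table.loc[~test]
        try:
            fitted = clone(model).fit(sub)
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"fold {f}: degenerate design ({exc})")
        predicted[test] = fitted.predict(table.loc[test])
    return pd.DataFrame({"observed": observed, "predicted": predicted,
                         "fold": folds}, index=table.index)
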
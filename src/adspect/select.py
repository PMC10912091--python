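"""Two-stage feature selection: one-way ANOVA screening, then ridge weighting.

Stage 1 tests every feature with a classical fixed-effects one-way ANOVA
across the four diagnostic groups and keeps features with p < alpha (0.05 by
default, no multiple-testing correction). Stage 2 fits a ridge regression of
one-hot group indicators on the standardized selected features and uses the
mean absolute coefficient across classes as a multiplicative feature weight.

:class:`AnovaRidgeSelector` packages both stages as a scikit-learn
transformer so selection can be nested inside cross-validation folds;
standardization statistics are always taken from the fitting subjects only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import Ridge

from .errors import AlignmentError, DegenerateInputError, DesignError, ParameterError
from .features import FeatureTable
from .schemes import CLASS_ORDER


@dataclass
class SelectionResult:
    """Per-feature screening statistics and (optionally) ridge weights."""

    f_statistic: np.ndarray
    p_value: np.ndarray
    selected: np.ndarray            # boolean mask, p < alpha
    alpha: float
    zero_variance: np.ndarray       # flagged columns whose p was forced to 1
    weights: np.ndarray | None = None   # per selected feature, aligned with mask order
    ridge_lambda: float | None = None
    keys: list | None = None


def _group_arrays(X: np.ndarray, labels: np.ndarray) -> list[np.ndarray]:
    groups = [X[labels == g] for g in CLASS_ORDER if np.any(labels == g)]
    if len(groups) < 2:
        raise DesignError("ANOVA requires at least 2 groups present")
    for g in groups:
        if g.shape[0] < 2:
            raise DesignError("every present group needs at least 2 subjects")
    return groups


def anova_screen(X, labels, alpha: float = 0.05, keys=None) -> SelectionResult:
    """One-way fixed-effects ANOVA per column; select columns with p < alpha.

    Columns with zero variance everywhere (F undefined) are flagged and
    assigned p = 1, never selected.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    groups = _group_arrays(X, labels)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat, p_val = stats.f_oneway(*groups, axis=0)
    f_stat = np.atleast_1d(np.asarray(f_stat, dtype=float))
    p_val = np.atleast_1d(np.asarray(p_val, dtype=float))
    zero_var = ~np.isfinite(f_stat)
    f_stat[zero_var] = 0.0
    p_val[zero_var] = 1.0
    selected = p_val < alpha
    return SelectionResult(f_stat, p_val, selected, alpha, zero_var, keys=keys)


def ridge_weights(X_selected, labels, ridge_lambda: float = 1.0) -> np.ndarray:
    """Ridge fit of one-hot group indicators on standardized selected columns.

    Returns the mean absolute coefficient across classes per column. Columns
    are standardized internally with the fitting subjects' statistics; the
    intercept is unpenalized.
    """
    if ridge_lambda <= 0:
        raise ParameterError("ridge lambda must be > 0")
    X = np.asarray(X_selected, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ParameterError("ridge weighting requires at least one selected column")
    labels = np.asarray(labels)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Z = (X - mean) / std
    onehot = np.stack([(labels == g).astype(float) for g in CLASS_ORDER], axis=1)
    model = Ridge(alpha=ridge_lambda, fit_intercept=True)
    model.fit(Z, onehot)
    return np.abs(model.coef_).mean(axis=0)


def apply_selection(table: FeatureTable, sel: SelectionResult) -> FeatureTable:
    """Restrict a table to the selected columns and multiply by their weights."""
    if sel.p_value.size != table.n_features:
        raise AlignmentError("selection was computed on a table with different keys")
    if sel.keys is not None and list(sel.keys) != list(table.values.columns):
        raise AlignmentError("selection keys do not match the table's columns")
    mask = sel.selected
    values = table.values.loc[:, mask]
    if sel.weights is not None:
        values = values * sel.weights
    return FeatureTable(values, table.labels, table.state)


def rank_by_pvalue(sel: SelectionResult, k: int | None = None) -> np.ndarray:
    """Feature indices by ascending p value; ties broken by canonical key order."""
    order = np.argsort(sel.p_value, kind="stable")
    if k is not None:
        order = order[: min(k, order.size)]
    return order


class AnovaRidgeSelector(BaseEstimator, TransformerMixin):
    """ANOVA screening + ridge weighting as a scikit-learn transformer.

    Parameters
    ----------
    alpha : significance level for the univariate screen (ignored if ``top_k``).
    ridge_lambda : L2 penalty of the weighting regression.
    top_k : if set, keep the k smallest-p features instead of thresholding at
        alpha (the feature-count-sweep variant).

    ``transform`` standardizes with the fitted statistics, restricts to the
    selected support and multiplies by the ridge weights. An empty support
    raises :class:`DegenerateInputError` at transform time — downstream
    classifiers must refuse an empty feature set.
    """

    def __init__(self, alpha: float = 0.05, ridge_lambda: float = 1.0,
                 top_k: int | None = None):
        self.alpha = alpha
        self.ridge_lambda = ridge_lambda
        self.top_k = top_k

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.top_k is not None and self.top_k < 1:
            raise ParameterError("top_k must be >= 1")
        result = anova_screen(X, y, alpha=self.alpha)
        if self.top_k is not None:
            mask = np.zeros(X.shape[1], dtype=bool)
            mask[rank_by_pvalue(result, self.top_k)] = True
            result.selected = mask
        self.f_statistic_ = result.f_statistic
        self.pvalues_ = result.p_value
        self.support_ = result.selected
        self.zero_variance_ = result.zero_variance
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        self.scale_ = scale
        self.weights_ = np.zeros(X.shape[1])
        if self.support_.any():
            Z = (X - self.mean_) / self.scale_
            self.weights_[self.support_] = _ridge_weights_standardized(
                Z[:, self.support_], y, self.ridge_lambda
            )
        self.n_features_in_ = X.shape[1]
        self.selection_ = result
        result.weights = self.weights_[self.support_]
        result.ridge_lambda = self.ridge_lambda
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise AlignmentError("transform input has a different number of features")
        if not self.support_.any():
            raise DegenerateInputError("no feature selected; classifiers must refuse")
        Z = (X - self.mean_) / self.scale_
        return Z[:, self.support_] * self.weights_[self.support_]


def _ridge_weights_standardized(Z, labels, ridge_lambda):
    if ridge_lambda <= 0:
        raise ParameterError("ridge lambda must be > 0")
    onehot = np.stack([(np.asarray(labels) == g).astype(float) for g in CLASS_ORDER],
                      axis=1)
    model = Ridge(alpha=ridge_lambda, fit_intercept=True)
    model.fit(Z, onehot)
    return np.abs(model.coef_).mean(axis=0)


def selection_summary(sel: SelectionResult, keys=None) -> dict:
    """Count selected features along each taxonomy axis (region/activity/ratio/band/epoch)."""
    keys = keys if keys is not None else sel.keys
    if keys is None:
        raise ParameterError("keys are required for a selection summary")
    axes: dict[str, dict[str, int]] = {
        "region": {}, "activity": {}, "ratio": {}, "band": {}, "epoch": {}
    }
    n_sel = 0
    for key, selected in zip(keys, sel.selected):
        if not selected:
            continue
        n_sel += 1
        parts = str(key).split(".")
        region, activity, ratio, band, epoch = parts[-5:]
        for axis, value in zip(axes, (region, activity, ratio, band, epoch)):
            axes[axis][value] = axes[axis].get(value, 0) + 1
    return {"n_selected": n_sel, "by_axis": axes}
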
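"""LOSO cross-validated multi-class evaluation with the full metric suite.

Leave-one-subject-out: one fold per subject, the remainder as training set.
In the default ``nested`` mode the ANOVA+ridge selection (and its
standardization) is refitted inside every training fold, so no information
from the held-out subject leaks into screening, scaling, weighting, or
fitting. ``paper`` mode fits the selection once on the whole cohort before
cross-validation — the apparent global-selection variant — and is provided
for fidelity comparisons only.

Metrics per class come from the one-vs-rest reduction of the 4x4 confusion
matrix: sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision
TP/(TP+FP), F1 as the harmonic mean of precision and sensitivity (all in
percent), plus one-vs-rest ROC AUC from the per-class membership scores.
Overall: accuracy (trace/total), Cohen's kappa from the row/column
marginals, and macro-F1.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import clone
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score

from .errors import DesignError, ParameterError
from .features import FeatureTable
from .models import decode_labels, encode_labels, make_model
from .schemes import CLASS_ORDER
from .select import AnovaRidgeSelector

logger = logging.getLogger(__name__)


# --- folds --------------------------------------------------------------------


def loso_folds(subject_ids) -> list[tuple[list, object]]:
    """One (train, test) fold per subject, ordered by subject id."""
    ids = list(subject_ids)
    if len(ids) < 2:
        raise DesignError("LOSO requires at least 2 subjects")
    if len(set(ids)) != len(ids):
        raise DesignError("duplicate subject ids")
    folds = []
    for test_id in sorted(ids):
        folds.append(([sid for sid in ids if sid != test_id], test_id))
    return folds


# --- metrics ------------------------------------------------------------------


def confusion(y_true, y_pred) -> np.ndarray:
    """4x4 confusion matrix; rows are true classes in the order SCD, naMCI, aMCI, AD."""
    y_true = _as_codes(y_true)
    y_pred = _as_codes(y_pred)
    if len(y_true) != len(y_pred):
        raise ParameterError("label vectors must have equal length")
    return _sk_confusion(y_true, y_pred, labels=list(range(len(CLASS_ORDER))))


def _as_codes(labels):
    labels = list(labels)
    if labels and isinstance(labels[0], str):
        return encode_labels(labels)
    return [int(v) for v in labels]


def _safe_ratio(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def per_class_metrics(cm: np.ndarray, class_index: int) -> dict:
    """One-vs-rest sensitivity/specificity/precision/F1 (percent) for one class.

    Undefined 0/0 ratios are reported as 0 with ``undefined=True``.
    """
    cm = np.asarray(cm)
    tp = cm[class_index, class_index]
    fn = cm[class_index].sum() - tp
    fp = cm[:, class_index].sum() - tp
    tn = cm.sum() - tp - fn - fp
    sens, f_sens = _safe_ratio(tp, tp + fn)
    spec, f_spec = _safe_ratio(tn, tn + fp)
    prec, f_prec = _safe_ratio(tp, tp + fp)
    if prec + sens == 0:
        f1, f_f1 = 0.0, True
    else:
        f1, f_f1 = 2.0 * prec * sens / (prec + sens), False
    return {
        "sensitivity": sens * 100.0,
        "specificity": spec * 100.0,
        "precision": prec * 100.0,
        "f1": f1 * 100.0,
        "undefined": bool(f_sens or f_spec or f_prec or f_f1),
    }


def accuracy_kappa(cm: np.ndarray) -> tuple[float, float]:
    """Overall accuracy in percent and Cohen's kappa from the marginals."""
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total <= 0:
        raise ParameterError("confusion matrix is empty")
    p_obs = np.trace(cm) / total
    p_exp = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / total**2
    if p_exp >= 1.0:
        kappa = 1.0 if p_obs >= 1.0 else 0.0
    else:
        kappa = (p_obs - p_exp) / (1.0 - p_exp)
    return p_obs * 100.0, kappa


def roc_auc(y_true, scores: np.ndarray, class_index: int) -> float:
    """One-vs-rest ROC AUC from the class's membership score column."""
    y = np.asarray(_as_codes(y_true))
    binary = (y == class_index).astype(int)
    if binary.min() == binary.max():
        return float("nan")
    return float(roc_auc_score(binary, np.asarray(scores)[:, class_index]))


@dataclass
class EvaluationReport:
    """Per-model, per-state LOSO results: confusion, per-class metrics, overall scores."""

    model: str
    state: str
    subject_ids: list
    true_labels: list
    predicted_labels: list
    scores: np.ndarray                      # subjects x 4 class-membership scores
    confusion_matrix: np.ndarray = field(init=False)
    per_class: dict = field(init=False)
    accuracy: float = field(init=False)
    kappa: float = field(init=False)
    macro_f1: float = field(init=False)

    def __post_init__(self) -> None:
        cm = confusion(self.true_labels, self.predicted_labels)
        self.confusion_matrix = cm
        self.per_class = {}
        for i, name in enumerate(CLASS_ORDER):
            metrics = per_class_metrics(cm, i)
            metrics["auc"] = roc_auc(self.true_labels, self.scores, i)
            self.per_class[name] = metrics
        self.accuracy, self.kappa = accuracy_kappa(cm)
        self.macro_f1 = float(np.mean([self.per_class[c]["f1"] for c in CLASS_ORDER]))

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "state": self.state,
            "class_order": list(CLASS_ORDER),
            "confusion_matrix": self.confusion_matrix.tolist(),
            "per_class": {
                name: {k: (None if isinstance(v, float) and np.isnan(v) else v)
                       for k, v in m.items()}
                for name, m in self.per_class.items()
            },
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "macro_f1": self.macro_f1,
            "subject_ids": list(self.subject_ids),
            "true_labels": list(self.true_labels),
            "predicted_labels": list(self.predicted_labels),
        }


# --- chance bounds ------------------------------------------------------------


def chance_upper_bound(labels, confidence: float = 0.95) -> float:
    """Upper binomial bound on the accuracy of any label-independent classifier.

    The best label-independent strategy matches the majority class, so the
    bound is the ``confidence`` quantile of Binomial(n, p_majority) / n.
    """
    labels = list(labels)
    n = len(labels)
    counts = [labels.count(g) for g in CLASS_ORDER]
    p0 = max(counts) / n
    return float(stats.binom.ppf(confidence, n, p0)) / n


# --- LOSO experiment ----------------------------------------------------------


def fit_predict(model, X_train, y_train, X_test, seed: int = 0):
    """Fit one estimator and return (predicted codes, per-class score rows).

    ``model`` may be a name from the model zoo or an unfitted sklearn
    estimator; scores are aligned to the full 4-class order and sum to 1.
    """
    if isinstance(model, str):
        model = make_model(model, seed=seed)
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if X_train.shape[1] == 0:
        raise ParameterError("refusing to fit on an empty feature set")
    y_codes = np.asarray(_as_codes(y_train))
    est = clone(model)
    est.fit(X_train, y_codes)
    proba = est.predict_proba(X_test)
    full = np.zeros((X_test.shape[0], len(CLASS_ORDER)))
    for j, cls in enumerate(est.classes_):
        full[:, int(cls)] = proba[:, j]
    pred = full.argmax(axis=1)
    return pred, full


def _state_matrix(table: FeatureTable):
    ids = table.subject_ids
    X = table.values.to_numpy(dtype=float)
    y = np.asarray(encode_labels(list(table.labels)))
    return ids, X, y


def _run_models_on_state(
    table: FeatureTable,
    model_names,
    mode: str,
    seed: int,
    alpha: float,
    ridge_lambda: float,
    top_k: int | None,
    model_kwargs: dict | None = None,
) -> dict[str, EvaluationReport]:
    if mode not in ("nested", "paper"):
        raise ParameterError(f"unknown selection mode {mode!r}")
    ids, X, y = _state_matrix(table)
    id_pos = {sid: i for i, sid in enumerate(ids)}
    folds = loso_folds(ids)
    model_kwargs = model_kwargs or {}
    estimators = {name: make_model(name, seed=seed, **model_kwargs) for name in model_names}

    global_selector = None
    if mode == "paper":
        global_selector = AnovaRidgeSelector(
            alpha=alpha, ridge_lambda=ridge_lambda, top_k=top_k
        ).fit(X, np.asarray(decode_labels(y)))

    preds = {name: [] for name in model_names}
    probs = {name: [] for name in model_names}
    true = []
    test_order = []
    cohort_classes = set(y.tolist())
    for train_ids, test_id in folds:
        t0 = time.perf_counter()
        tr = np.array([id_pos[s] for s in train_ids])
        te = np.array([id_pos[test_id]])
        if set(y[tr].tolist()) != cohort_classes:
            raise DesignError(
                f"fold {test_id}: a class present in the cohort is missing from training"
            )
        if mode == "nested":
            selector = AnovaRidgeSelector(
                alpha=alpha, ridge_lambda=ridge_lambda, top_k=top_k
            ).fit(X[tr], np.asarray(decode_labels(y[tr])))
        else:
            selector = global_selector
        X_tr = selector.transform(X[tr])
        X_te = selector.transform(X[te])
        for name in model_names:
            pred, score = fit_predict(estimators[name], X_tr, y[tr], X_te, seed=seed)
            preds[name].append(int(pred[0]))
            probs[name].append(score[0])
        true.append(int(y[te][0]))
        test_order.append(test_id)
        logger.debug(
            "fold %s: %d features selected, %.3f s",
            test_id, int(selector.support_.sum()), time.perf_counter() - t0,
        )

    reports = {}
    for name in model_names:
        reports[name] = EvaluationReport(
            model=name,
            state=table.state,
            subject_ids=test_order,
            true_labels=decode_labels(true),
            predicted_labels=decode_labels(preds[name]),
            scores=np.asarray(probs[name]),
        )
    return reports


def run_experiment(
    tables: dict[str, FeatureTable],
    models=("cKNN",),
    mode: str = "nested",
    seed: int = 0,
    alpha: float = 0.05,
    ridge_lambda: float = 1.0,
    top_k: int | None = None,
    model_kwargs: dict | None = None,
) -> dict[tuple[str, str], EvaluationReport]:
    """Full LOSO loop over states and models; deterministic given ``seed``.

    ``tables`` maps state names (e.g. 'resting', 'encoding') to feature
    tables over the same subjects. Selection is refitted per fold in
    ``nested`` mode (default) or fitted once per state in ``paper`` mode.
    """
    for name in models:
        make_model(name, seed=seed)  # validate names early
    out: dict[tuple[str, str], EvaluationReport] = {}
    for state, table in tables.items():
        state_reports = _run_models_on_state(
            table, list(models), mode, seed, alpha, ridge_lambda, top_k, model_kwargs
        )
        for name, report in state_reports.items():
            out[(name, state)] = report
    return out


def f1_vs_nfeatures(
    table: FeatureTable,
    model: str = "cKNN",
    k_grid=(1, 2, 5, 10, 20, 50),
    mode: str = "nested",
    seed: int = 0,
    ridge_lambda: float = 1.0,
) -> dict[int, float]:
    """Macro-F1 as a function of the number of lowest-p features used.

    For each k the k features with the smallest ANOVA p values (ties broken
    by canonical key order) are kept, ridge-weighted, and classified under
    LOSO.
    """
    curve: dict[int, float] = {}
    for k in k_grid:
        if k < 1:
            raise ParameterError("the feature-count grid must contain k >= 1")
        reports = _run_models_on_state(
            table, [model], mode, seed, alpha=1.0, ridge_lambda=ridge_lambda, top_k=int(k)
        )
        curve[int(k)] = reports[model].macro_f1
    return curve
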
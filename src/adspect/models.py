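"""Factory for the nine classical classifiers.

Names follow the field's shorthand: polynomial-kernel SVMs of degree 2/3
(2SVM, 3SVM), k-nearest neighbours with cosine or Euclidean metric (cKNN,
EuKNN), a random-subspace ensemble of discriminant learners (partEns),
single-hidden-layer networks of 10 or 100 units and a 10+10 double layer
(narNN, wideNN, doubleNN), and LDA. Hyperparameters are common-preset
defaults: k=10, SVM C=1, 30 ensemble members on half-dimensional subspaces,
log-loss network training with LBFGS (the usual preset for small-sample
network classifiers) capped at 1000 iterations.

Labels are handled as integer codes 0..3 along the clinical ordering
SCD < naMCI < aMCI < AD, so sklearn's smallest-index tie-breaking resolves
ties toward the class earliest in that order.
"""

from __future__ import annotations

from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import BaggingClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .errors import ParameterError
from .schemes import CLASS_ORDER

MODEL_NAMES: tuple[str, ...] = (
    "2SVM", "3SVM", "cKNN", "EuKNN", "partEns", "narNN", "wideNN", "doubleNN", "LDA",
)


def encode_labels(labels):
    """Map group names to integer codes along the clinical class order."""
    index = {g: i for i, g in enumerate(CLASS_ORDER)}
    try:
        return [index[g] for g in labels]
    except KeyError as exc:
        raise ParameterError(f"unknown group label {exc.args[0]!r}") from None


def decode_labels(codes):
    return [CLASS_ORDER[int(c)] for c in codes]


def make_model(
    name: str,
    seed: int = 0,
    n_neighbors: int = 10,
    svm_c: float = 1.0,
    n_estimators: int = 30,
    max_iter: int = 1000,
):
    """Build an unfitted sklearn estimator for one of the nine model names.

    Every estimator exposes ``predict_proba`` so per-class membership scores
    (summing to 1) are available for ROC analysis: neighbour vote fractions
    for kNN, pairwise-coupled probabilities for the SVMs, posteriors for LDA,
    and softmax/normalized outputs for the networks and the ensemble.
    """
    if name == "2SVM" or name == "3SVM":
        return SVC(
            kernel="poly",
            degree=2 if name == "2SVM" else 3,
            C=svm_c,
            coef0=1.0,
            gamma="scale",
            probability=True,
            random_state=seed,
        )
    if name == "cKNN":
        return KNeighborsClassifier(n_neighbors=n_neighbors, metric="cosine")
    if name == "EuKNN":
        return KNeighborsClassifier(n_neighbors=n_neighbors, metric="euclidean")
    if name == "partEns":
        return BaggingClassifier(
            estimator=LinearDiscriminantAnalysis(),
            n_estimators=n_estimators,
            max_features=0.5,
            bootstrap=False,
            random_state=seed,
        )
    if name in ("narNN", "wideNN", "doubleNN"):
        sizes = {"narNN": (10,), "wideNN": (100,), "doubleNN": (10, 10)}[name]
        return MLPClassifier(
            hidden_layer_sizes=sizes, solver="lbfgs", max_iter=max_iter,
            random_state=seed,
        )
    if name == "LDA":
        return LinearDiscriminantAnalysis()
    raise ParameterError(f"unknown model name {name!r}; choose from {MODEL_NAMES}")
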
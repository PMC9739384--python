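"""Classifiers for the behavior-recognition task.

The Gaussian naive Bayes model is implemented here from its defining
formula — per-class feature likelihoods

``P(x_i | c) = exp(-(x_i - mean_{i,c})^2 / (2 sigma^2_{i,c}))
/ sqrt(2 π sigma^2_{i,c})``

multiplied under the (naive) feature-independence assumption and
combined with class priors — because it is the model under study. The
three comparison classifiers (RBF-kernel SVM, K-nearest neighbors,
depth-limited decision tree) delegate to scikit-learn behind the same
fit/predict surface, with the study's hyperparameters as defaults:
``C = 10, gamma = 1`` for the SVM, ``max_depth = 5`` for the tree, and
``K = round(sqrt(n_train))`` for KNN. Distance- and kernel-based
methods (KNN, SVM) get a z-score standardizer fitted on the training
fold; GNB and the tree operate on unscaled features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .exceptions import ConfigurationError, InvalidInputError

__all__ = [
    "GaussianNaiveBayes",
    "ClassifierSpec",
    "default_specs",
    "knn_k",
    "gnb_fit",
    "gnb_predict",
    "train_classifier",
    "grid_search_svm",
]

_GNB_FORMAT = "imuquat-gnb"
_GNB_VERSION = 1


class GaussianNaiveBayes:
    """Gaussian naive Bayes with per-class diagonal Gaussians.

    Priors are class frequencies; means and variances are per-class
    sample moments (population normalization). Variances are floored at
    ``var_smoothing`` times the largest single-feature variance of the
    training data, so constant features (a quaternion component that
    never moves in a near-still class) cannot produce infinite
    densities. Posteriors are evaluated in log space to avoid
    underflow; ties are broken by class order (sorted labels).
    """

    def __init__(self, var_smoothing: float = 1e-9):
        self.var_smoothing = var_smoothing
        self.classes_: Optional[np.ndarray] = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GaussianNaiveBayes":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        if len(X) != len(y):
            raise InvalidInputError("X and y length mismatch")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise InvalidInputError("need at least two classes")
        if counts.min() < 2:
            raise InvalidInputError("need at least two samples per class")
        self.classes_ = classes
        self.priors_ = counts / len(y)
        self.means_ = np.stack([X[y == c].mean(axis=0) for c in classes])
        self.variances_ = np.stack([X[y == c].var(axis=0) for c in classes])
        max_var = float(X.var(axis=0).max())
        eps = self.var_smoothing * (max_var if max_var > 0 else 1.0)
        self.variances_ = np.maximum(self.variances_, eps)
        return self

    def _check_fitted(self) -> None:
        if self.classes_ is None:
            raise InvalidInputError("model is not fitted")

    def joint_log_likelihood(self, X: np.ndarray) -> np.ndarray:
        """Unnormalized log posterior: log prior + sum of log likelihoods."""
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.means_.shape[1]:
            raise InvalidInputError(
                f"expected {self.means_.shape[1]} features, got {X.shape[1]}"
            )
        diff = X[:, np.newaxis, :] - self.means_[np.newaxis, :, :]
        log_lik = -0.5 * (
            np.log(2.0 * np.pi * self.variances_)[np.newaxis]
            + diff**2 / self.variances_[np.newaxis]
        ).sum(axis=-1)
        return np.log(self.priors_)[np.newaxis] + log_lik

    def predict_log_proba(self, X: np.ndarray) -> np.ndarray:
        jll = self.joint_log_likelihood(X)
        return jll - logsumexp(jll, axis=1, keepdims=True)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return np.exp(self.predict_log_proba(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        # np.argmax returns the first maximum: ties go to class order.
        return self.classes_[np.argmax(self.joint_log_likelihood(X), axis=1)]

    # -- declarative persistence ------------------------------------------

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "format": _GNB_FORMAT,
            "version": _GNB_VERSION,
            "var_smoothing": self.var_smoothing,
            "classes": self.classes_.tolist(),
            "priors": self.priors_.tolist(),
            "means": self.means_.tolist(),
            "variances": self.variances_.tolist(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GaussianNaiveBayes":
        if data.get("format") != _GNB_FORMAT:
            raise ConfigurationError("not a serialized GNB model")
        if data.get("version") != _GNB_VERSION:
            raise ConfigurationError(f"unsupported model version {data.get('version')}")
        model = cls(var_smoothing=data["var_smoothing"])
        model.classes_ = np.asarray(data["classes"])
        model.priors_ = np.asarray(data["priors"], dtype=float)
        model.means_ = np.asarray(data["means"], dtype=float)
        model.variances_ = np.asarray(data["variances"], dtype=float)
        return model

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "GaussianNaiveBayes":
        return cls.from_dict(json.loads(Path(path).read_text()))


def gnb_fit(X: np.ndarray, y: np.ndarray, var_smoothing: float = 1e-9) -> GaussianNaiveBayes:
    """Fit a Gaussian naive Bayes model (functional wrapper)."""
    return GaussianNaiveBayes(var_smoothing=var_smoothing).fit(X, y)


def gnb_predict(model: GaussianNaiveBayes, x: np.ndarray) -> Tuple[object, np.ndarray]:
    """Classify one feature vector; returns (label, per-class posterior)."""
    x = np.asarray(x, dtype=float).reshape(1, -1)
    post = model.predict_proba(x)[0]
    return model.classes_[int(np.argmax(post))], post


def knn_k(n_train: int) -> int:
    """Neighbor count rule ``K = round(sqrt(n_train))``."""
    if n_train < 1:
        raise InvalidInputError("n_train must be positive")
    return max(1, int(round(np.sqrt(n_train))))


class _SqrtRuleKNN:
    """KNN whose K defaults to round(sqrt(n_train)), set at fit time."""

    def __init__(self, k: Optional[int] = None):
        self.k = k

    def fit(self, X, y):
        self.n_neighbors_ = self.k if self.k is not None else knn_k(len(X))
        self._pipe = make_pipeline(
            StandardScaler(), KNeighborsClassifier(n_neighbors=self.n_neighbors_)
        ).fit(X, y)
        return self

    def predict(self, X):
        return self._pipe.predict(X)


@dataclass(frozen=True)
class ClassifierSpec:
    """Declarative description of a classifier and its hyperparameters."""

    kind: str
    params: Dict[str, object] = field(default_factory=dict)

    _KINDS = ("gnb", "svm_rbf", "knn", "dtree")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ConfigurationError(f"unsupported classifier kind {self.kind!r}")


def default_specs() -> List[ClassifierSpec]:
    """The four classifiers of the comparison, with study defaults."""
    return [
        ClassifierSpec("gnb"),
        ClassifierSpec("svm_rbf", {"C": 10.0, "gamma": 1.0}),
        ClassifierSpec("knn"),
        ClassifierSpec("dtree", {"max_depth": 5}),
    ]


def train_classifier(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray, seed: int = 0):
    """Fit the classifier described by ``spec``; returns a fitted model
    exposing ``predict``.

    ``gnb`` uses the in-house implementation; the other kinds delegate
    to scikit-learn (with a training-fold standardizer for SVM/KNN).
    Deterministic for a fixed seed.
    """
    p = dict(spec.params)
    if spec.kind == "gnb":
        model = GaussianNaiveBayes(var_smoothing=p.pop("var_smoothing", 1e-9))
    elif spec.kind == "svm_rbf":
        model = make_pipeline(
            StandardScaler(),
            SVC(
                C=p.pop("C", 10.0),
                gamma=p.pop("gamma", 1.0),
                kernel="rbf",
                cache_size=p.pop("cache_size", 512),
                random_state=seed,
            ),
        )
    elif spec.kind == "knn":
        model = _SqrtRuleKNN(k=p.pop("k", None))
    elif spec.kind == "dtree":
        model = DecisionTreeClassifier(max_depth=p.pop("max_depth", 5), random_state=seed)
    else:  # pragma: no cover - guarded by ClassifierSpec
        raise ConfigurationError(f"unsupported classifier kind {spec.kind!r}")
    if p:
        raise ConfigurationError(f"unknown parameters for {spec.kind}: {sorted(p)}")
    return model.fit(X, y)


def grid_search_svm(
    X: np.ndarray,
    y: np.ndarray,
    Cs: Sequence[float] = (0.1, 1.0, 10.0, 100.0),
    gammas: Sequence[float] = (0.01, 0.1, 1.0, 10.0),
    k: int = 3,
    seed: int = 0,
) -> Tuple[Dict[str, float], float]:
    """Exhaustive (C, gamma) grid search scored by cross-validated macro
    F-score; returns the best parameter dict and its score.

    The default comparison pipeline skips the search and uses the fixed
    best parameters ``C = 10, gamma = 1``.
    """
    from .evaluation import cross_validate  # local import: avoids a cycle
    from .features import FeatureMatrix, kfold_split

    fm = FeatureMatrix(X=X, y=y)
    folds = kfold_split(fm, k=k, seed=seed)
    best: Tuple[float, Dict[str, float]] = (-np.inf, {})
    for C in Cs:
        for gamma in gammas:
            spec = ClassifierSpec("svm_rbf", {"C": float(C), "gamma": float(gamma)})
            report = cross_validate(spec, fm, folds, seed=seed)
            if report.macro_fscore > best[0]:
                best = (report.macro_fscore, {"C": float(C), "gamma": float(gamma)})
    return best[1], best[0]
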
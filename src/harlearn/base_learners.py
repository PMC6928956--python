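"""Weak base classifiers with a uniform posterior-producing contract.

Three kinds are supported — linear discriminant analysis (LDA), quadratic
discriminant analysis (QDA) and a classification tree (CART).  Every fitted
model exposes ``predict_posterior`` returning a valid probability vector over
its class list; the hard prediction is the argmax.

LDA and QDA are implemented directly as Gaussian discriminants: personal
training chunks are small and noisy, so QDA per-class covariances are
shrunk toward their own diagonal, Σ_c ← (1−λ)Σ_c + λ·diag(Σ_c), a
regularisation that keeps per-feature scales intact (unlike shrinking
toward a scaled identity).  The direct implementation also provides the
closed-form pieces the batched feature-selection scorer in
:mod:`harlearn.training` reuses.  CART wraps scikit-learn's decision tree
with Laplace-smoothed leaf-count posteriors so leaf probabilities are never
exactly 0 or 1, which would make posterior-confidence thresholds degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .errors import DataError, TrainingError

Kind = Literal["lda", "qda", "cart"]
Origin = Literal["user_independent", "personal"]

#: Relative ridge added to covariance diagonals for numerical stability
#: (bootstrap resamples can make a selected feature nearly constant).
_RIDGE = 1e-6


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _check_labels(y: np.ndarray) -> np.ndarray:
    classes = np.unique(y)
    if classes.size < 2:
        raise TrainingError("degenerate chunk: fewer than 2 classes in y")
    if len(y) < classes.size:
        raise TrainingError(
            f"fewer samples ({len(y)}) than classes ({classes.size})"
        )
    return classes


class LDAClassifier:
    """Gaussian discriminant with a pooled within-class covariance.

    Priors are the training class frequencies; the pooled covariance gets a
    small relative ridge on its diagonal.
    """

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LDAClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        if len(X) < 2:
            raise TrainingError("need at least 2 samples")
        classes = _check_labels(y)
        n, p = X.shape
        means = np.empty((classes.size, p))
        scatter = np.zeros((p, p))
        counts = np.empty(classes.size)
        for k, c in enumerate(classes):
            Xc = X[y == c]
            counts[k] = len(Xc)
            means[k] = Xc.mean(axis=0)
            d = Xc - means[k]
            scatter += d.T @ d
        dof = max(n - classes.size, 1)
        cov = scatter / dof
        tr = np.trace(cov)
        cov[np.diag_indices_from(cov)] += _RIDGE * max(tr / p, 1.0e-6)
        self.classes_ = classes
        self.priors_ = counts / n
        self.means_ = means
        self.covariance_ = cov
        # discriminant: x·W_k + b_k with W = Σ⁻¹ μ_kᵀ
        self.coef_ = np.linalg.solve(cov, means.T)  # (p, K)
        self.intercept_ = (
            -0.5 * np.einsum("kp,pk->k", means, self.coef_) + np.log(self.priors_)
        )
        return self

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def predict_posterior(self, X: np.ndarray) -> np.ndarray:
        return _softmax(self.decision_scores(X))


class QDAClassifier:
    """Gaussian discriminant with per-class shrunk covariances.

    ``shrinkage`` is the weight λ of the diagonal target in
    Σ_c ← (1−λ)Σ_c + λ·diag(Σ_c); the default 0.1 keeps small personal
    chunks from producing singular class covariances.
    """

    def __init__(self, shrinkage: float = 0.1) -> None:
        if not 0 <= shrinkage <= 1:
            raise TrainingError("shrinkage must lie in [0, 1]")
        self.shrinkage = shrinkage

    def fit(self, X: np.ndarray, y: np.ndarray) -> "QDAClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        classes = _check_labels(y)
        n, p = X.shape
        self.classes_ = classes
        self.means_ = np.empty((classes.size, p))
        self.priors_ = np.empty(classes.size)
        self._chol = []
        self._logdet = np.empty(classes.size)
        for k, c in enumerate(classes):
            Xc = X[y == c]
            if len(Xc) < 2:
                raise TrainingError(
                    f"QDA needs >= 2 samples per class (class {c!r} has {len(Xc)})"
                )
            self.priors_[k] = len(Xc) / n
            self.means_[k] = Xc.mean(axis=0)
            d = Xc - self.means_[k]
            cov = d.T @ d / (len(Xc) - 1)
            diag = np.diag(np.diag(cov))
            cov = (1 - self.shrinkage) * cov + self.shrinkage * diag
            tr = np.trace(cov)
            cov[np.diag_indices_from(cov)] += _RIDGE * max(tr / p, 1.0e-6)
            L = np.linalg.cholesky(cov)
            self._chol.append(L)
            self._logdet[k] = 2 * np.sum(np.log(np.diag(L)))
        return self

    def predict_posterior(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        scores = np.empty((len(X), self.classes_.size))
        for k in range(self.classes_.size):
            d = (X - self.means_[k]).T  # (p, n)
            z = np.linalg.solve(self._chol[k], d)
            maha = np.sum(z ** 2, axis=0)
            scores[:, k] = (
                -0.5 * maha - 0.5 * self._logdet[k] + np.log(self.priors_[k])
            )
        return _softmax(scores)


class CARTClassifier:
    """Decision tree with Laplace-smoothed leaf posteriors.

    Posterior for a sample reaching a leaf with per-class counts n_c is
    (n_c + 1) / (n_leaf + K), so probabilities are never exactly 0 or 1.
    """

    def __init__(self, max_depth: int = 6, min_samples_leaf: int = 3,
                 random_state: int = 0) -> None:
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CARTClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        classes = _check_labels(y)
        self.classes_ = classes
        y_idx = np.searchsorted(classes, y)
        self._tree = DecisionTreeClassifier(
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.random_state,
        ).fit(X, y_idx)
        leaves = self._tree.apply(X)
        K = classes.size
        self._leaf_counts = {}
        for leaf in np.unique(leaves):
            mask = leaves == leaf
            counts = np.bincount(y_idx[mask], minlength=K).astype(float)
            self._leaf_counts[int(leaf)] = (counts + 1.0) / (mask.sum() + K)
        return self

    def predict_posterior(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        leaves = self._tree.apply(X)
        return np.vstack([self._leaf_counts[int(l)] for l in leaves])


_CLASSIFIERS = {"lda": LDAClassifier, "qda": QDAClassifier, "cart": CARTClassifier}


@dataclass
class BaseModel:
    """A fitted weak classifier plus its provenance.

    ``selected_features`` indexes into the global feature vector; the model
    applies this restriction itself, so callers always pass full-width
    feature matrices to :meth:`predict_posterior`.
    """

    kind: Kind
    origin: Origin
    selected_features: np.ndarray
    class_list: list[str]
    clf: object
    n_features_total: int
    fitted: bool = field(default=True)

    def __post_init__(self) -> None:
        idx = np.asarray(self.selected_features, dtype=int)
        if idx.size == 0:
            raise TrainingError("selected_features must be non-empty")
        if len(np.unique(idx)) != idx.size:
            raise TrainingError("selected_features must be unique")
        if idx.min() < 0 or idx.max() >= self.n_features_total:
            raise TrainingError("selected_features out of range")
        self.selected_features = idx

    def predict_posterior(self, X: np.ndarray) -> np.ndarray:
        """Posterior matrix (n, K) over ``class_list`` for full-width X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_total:
            raise DataError(
                f"feature dimension {X.shape[1]} != expected {self.n_features_total}"
            )
        post = self.clf.predict_posterior(X[:, self.selected_features])
        return post / post.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        post = self.predict_posterior(X)
        return np.asarray(self.class_list, dtype=object)[post.argmax(axis=1)]


def make_classifier(kind: Kind, options: dict | None = None,
                    random_state: int = 0):
    """Instantiate an unfitted classifier of the given kind."""
    options = dict(options or {})
    if kind == "lda":
        return LDAClassifier()
    if kind == "qda":
        return QDAClassifier(shrinkage=options.get("shrinkage", 0.1))
    if kind == "cart":
        return CARTClassifier(
            max_depth=options.get("max_depth", 6),
            min_samples_leaf=options.get("min_samples_leaf", 3),
            random_state=random_state,
        )
    raise TrainingError(f"unknown classifier kind {kind!r}")


def fit_base(
    kind: Kind,
    X: np.ndarray,
    y: np.ndarray,
    *,
    origin: Origin = "user_independent",
    selected_features=None,
    n_features_total: int | None = None,
    options: dict | None = None,
    random_state: int = 0,
) -> BaseModel:
    """Fit one base model on an (already feature-restricted) matrix.

    ``X`` holds only the columns named by ``selected_features`` (default: all
    columns of a ``n_features_total``-wide global vector).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    if selected_features is None:
        selected_features = np.arange(X.shape[1])
    if n_features_total is None:
        n_features_total = X.shape[1]
    clf = make_classifier(kind, options, random_state=random_state)
    clf.fit(X, y)
    return BaseModel(
        kind=kind,
        origin=origin,
        selected_features=np.asarray(selected_features, dtype=int),
        class_list=[str(c) for c in clf.classes_],
        clf=clf,
        n_features_total=int(n_features_total),
    )
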
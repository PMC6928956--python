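"""Building one base model from a labeled chunk.

Personal chunks are small, so the pipeline is: Gaussian noise injection in
feature space (append R noisy copies of every window, per-feature SD scaled
to α times that feature's in-chunk SD) → bootstrap sampling with replacement
→ sequential forward feature selection (SFS) → fit.  User-independent models
skip noise injection and bootstrap the pooled multi-subject data at its full
size S.

SFS is a wrapper: starting from the empty set it repeatedly adds the feature
that maximises mean stratified k-fold cross-validated balanced accuracy of
the classifier kind being trained, stopping at ``sfs_max_features`` or when
the gain drops to ``sfs_min_gain`` or below; score ties resolve to the
smallest feature index.  For LDA the fold scores are computed with a batched
closed-form evaluator (class means plus lazily-built within-class scatter
columns), which makes wrapper selection over a ~200-feature bank cheap; QDA
and CART use a generic per-candidate loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .base_learners import BaseModel, Kind, Origin, fit_base, make_classifier, _RIDGE
from .errors import ConfigError, DataError, TrainingError
from .features import FeatureSet
from .metrics import balanced_accuracy

Hook = Callable[[str, dict], None]


@dataclass(frozen=True)
class TrainConfig:
    """Chunk-to-base-model training parameters.

    ``bootstrap_size_rule`` controls the bootstrap draw count for personal
    chunks: ``original_size`` draws as many rows as the chunk had before
    noise injection; ``pool_size`` draws as many as the augmented pool holds.
    User-independent models always bootstrap at the pooled-data size.
    """

    n_models_per_chunk: int = 3
    bootstrap_size_rule: Literal["original_size", "pool_size"] = "original_size"
    noise_copies: int = 2
    noise_scale: float = 0.1
    sfs_max_features: int = 10
    sfs_folds: int = 3
    sfs_min_gain: float = 0.0
    classifier_options: dict | None = None

    def __post_init__(self) -> None:
        if self.noise_copies < 0:
            raise ConfigError("noise_copies must be >= 0")
        if self.noise_scale < 0:
            raise ConfigError("noise_scale must be >= 0")
        if self.sfs_max_features < 1:
            raise ConfigError("sfs_max_features must be >= 1")
        if self.sfs_folds < 2:
            raise ConfigError("sfs_folds must be >= 2")
        if self.bootstrap_size_rule not in ("original_size", "pool_size"):
            raise ConfigError(
                f"bootstrap_size_rule: unknown rule {self.bootstrap_size_rule!r}"
            )


def noise_inject(chunk: FeatureSet, R: int, alpha: float,
                 rng: np.random.Generator) -> FeatureSet:
    """Append R noisy copies of every window to increase size and variation.

    Copy features are original + N(0, α·sd_f) per feature f, with sd_f the
    feature's SD within the chunk; labels are copied unchanged.
    """
    if alpha < 0:
        raise ConfigError("noise_scale must be >= 0")
    if len(chunk) == 0:
        raise DataError("noise_inject: empty chunk")
    if R == 0:
        return chunk
    sd = chunk.X.std(axis=0)
    parts = [chunk]
    for _ in range(R):
        noise = rng.normal(0.0, 1.0, size=chunk.X.shape) * (alpha * sd)
        parts.append(FeatureSet(
            subject_ids=chunk.subject_ids,
            w=chunk.w,
            X=chunk.X + noise,
            labels=chunk.labels,
            feature_names=chunk.feature_names,
        ))
    return FeatureSet.concat(parts)


def bootstrap_sample(pool: FeatureSet, size: int,
                     rng: np.random.Generator) -> FeatureSet:
    """Draw ``size`` rows uniformly with replacement (w indices preserved)."""
    if len(pool) == 0:
        raise DataError("bootstrap_sample: empty pool")
    if size < 1:
        raise ConfigError("bootstrap size must be >= 1")
    idx = rng.integers(0, len(pool), size=size)
    return pool.select(idx)


# ---------------------------------------------------------------------------
# Sequential forward selection
# ---------------------------------------------------------------------------

def _stratified_folds(y_idx: np.ndarray, n_folds: int, seed: int):
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        # bootstrap resamples of small chunks can leave a class with fewer
        # members than folds; stratification then degrades gracefully
        warnings.filterwarnings("ignore", category=UserWarning,
                                module="sklearn.model_selection")
        return list(skf.split(np.zeros(len(y_idx)), y_idx))


class _LDAFoldScorer:
    """Closed-form batched LDA CV scoring for one fold.

    Keeps class means over the training split and builds within-class
    scatter columns lazily, so evaluating all candidate one-feature
    extensions of the current selection costs O(n·p) instead of O(n·p²).
    """

    def __init__(self, X, y_idx, train, val, n_classes):
        self.Xt, self.yt = X[train], y_idx[train]
        self.Xv, self.yv = X[val], y_idx[val]
        K, p = n_classes, X.shape[1]
        counts = np.bincount(self.yt, minlength=K).astype(float)
        self.present = np.flatnonzero(counts > 0)
        means = np.zeros((K, p))
        for k in self.present:
            means[k] = self.Xt[self.yt == k].mean(axis=0)
        self.counts, self.means = counts, means
        self.diag_w = (self.Xt ** 2).sum(axis=0) - (counts[:, None] * means ** 2).sum(axis=0)
        self.dof = max(len(self.Xt) - len(self.present), 1)
        self.log_priors = np.log(counts[self.present] / len(self.Xt))
        self._cols: dict[int, np.ndarray] = {}
        self.val_classes = np.unique(self.yv)

    def col(self, f: int) -> np.ndarray:
        if f not in self._cols:
            self._cols[f] = (
                self.Xt.T @ self.Xt[:, f]
                - self.means.T @ (self.counts * self.means[:, f])
            )
        return self._cols[f]

    def candidate_scores(self, selected: list[int], cand: np.ndarray) -> np.ndarray:
        """Balanced accuracy on the validation split for each candidate
        feature appended to ``selected``."""
        s, F = len(selected), len(cand)
        Kp = len(self.present)
        Mp = self.means[self.present]
        A = np.array([[self.col(a)[b] for b in selected] for a in selected])
        b = (np.stack([self.col(a)[cand] for a in selected], axis=0)
             if s else np.zeros((0, F)))
        d = self.diag_w[cand]
        cov = np.empty((F, s + 1, s + 1))
        cov[:, :s, :s] = A / self.dof
        cov[:, :s, s] = (b / self.dof).T
        cov[:, s, :s] = (b / self.dof).T
        cov[:, s, s] = d / self.dof
        tr = np.einsum("fii->f", cov)
        ridge = _RIDGE * np.maximum(tr / (s + 1), 1e-6)
        cov[:, np.arange(s + 1), np.arange(s + 1)] += ridge[:, None]
        mu = np.empty((F, Kp, s + 1))
        mu[:, :, :s] = Mp[:, selected][None, :, :]
        mu[:, :, s] = Mp[:, cand].T
        W = np.linalg.solve(cov, mu.transpose(0, 2, 1))  # (F, s+1, Kp)
        const = -0.5 * np.einsum("fkp,fpk->fk", mu, W) + self.log_priors[None, :]
        Zs = self.Xv[:, selected]
        logits = (
            np.einsum("ns,fsk->fnk", Zs, W[:, :s, :])
            + self.Xv[:, cand].T[:, :, None] * W[:, s, :][:, None, :]
            + const[:, None, :]
        )
        preds = self.present[logits.argmax(axis=2)]  # (F, n_val) global class ids
        acc = np.zeros(F)
        for k in self.val_classes:
            mask = self.yv == k
            acc += (preds[:, mask] == k).mean(axis=1)
        return acc / len(self.val_classes)


def _sfs_lda(X, y_idx, n_classes, folds, max_features, min_gain):
    scorers = [_LDAFoldScorer(X, y_idx, tr, va, n_classes) for tr, va in folds]
    p = X.shape[1]
    selected: list[int] = []
    current = -np.inf
    while len(selected) < max_features:
        cand = np.setdiff1d(np.arange(p), selected)
        if cand.size == 0:
            break
        scores = np.zeros(cand.size)
        for sc in scorers:
            scores += sc.candidate_scores(selected, cand)
        scores /= len(scorers)
        best = scores.max()
        if best - current <= min_gain and selected:
            break
        selected.append(int(cand[np.flatnonzero(scores == best)[0]]))
        current = best
    return selected


def _sfs_generic(X, y, kind, folds, max_features, min_gain, options, seed):
    p = X.shape[1]
    selected: list[int] = []
    current = -np.inf
    while len(selected) < max_features:
        cand = [f for f in range(p) if f not in selected]
        if not cand:
            break
        scores = np.zeros(len(cand))
        for i, f in enumerate(cand):
            cols = selected + [f]
            fold_scores = []
            for tr, va in folds:
                clf = make_classifier(kind, options, random_state=seed)
                try:
                    clf.fit(X[np.ix_(tr, cols)], y[tr])
                except TrainingError:
                    fold_scores.append(0.0)
                    continue
                post = clf.predict_posterior(X[np.ix_(va, cols)])
                preds = np.asarray(clf.classes_, dtype=object)[post.argmax(axis=1)]
                fold_scores.append(balanced_accuracy(y[va], preds))
            scores[i] = np.mean(fold_scores)
        best = scores.max()
        if best - current <= min_gain and selected:
            break
        selected.append(cand[int(np.flatnonzero(scores == best)[0])])
        current = best
    return selected


def sfs_select(X: np.ndarray, y: np.ndarray, kind: Kind, cfg: TrainConfig,
               rng: np.random.Generator) -> list[int]:
    """Greedy forward feature selection by stratified CV balanced accuracy.

    Returns the selected feature indices in selection order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    classes = np.unique(y)
    if classes.size < 2:
        raise TrainingError("degenerate chunk: fewer than 2 classes for SFS")
    if len(y) < 2 * cfg.sfs_folds:
        raise TrainingError(
            f"need at least {2 * cfg.sfs_folds} samples for {cfg.sfs_folds}-fold SFS"
        )
    y_idx = np.searchsorted(classes, y)
    fold_seed = int(rng.integers(2 ** 31 - 1))
    folds = _stratified_folds(y_idx, cfg.sfs_folds, fold_seed)
    if kind == "lda":
        return _sfs_lda(X, y_idx, classes.size, folds,
                        cfg.sfs_max_features, cfg.sfs_min_gain)
    return _sfs_generic(X, y, kind, folds, cfg.sfs_max_features,
                        cfg.sfs_min_gain, cfg.classifier_options, fold_seed)


def train_base_model(
    chunk: FeatureSet,
    kind: Kind,
    origin: Origin,
    cfg: TrainConfig,
    rng: np.random.Generator,
    hooks: list[Hook] | None = None,
) -> BaseModel:
    """Train one base model from a labeled chunk (or the UI pool).

    Personal chunks go through noise injection → bootstrap → SFS → fit; the
    user-independent pool skips noise injection and bootstraps at its own
    size.  ``hooks`` receive ``(stage, payload)`` for each pipeline stage.
    """
    def emit(stage: str, **payload) -> None:
        for h in hooks or []:
            h(stage, payload)

    if len(np.unique(chunk.labels)) < 2:
        raise TrainingError("degenerate chunk: fewer than 2 classes")
    if origin == "personal":
        augmented = noise_inject(chunk, cfg.noise_copies, cfg.noise_scale, rng)
        emit("noise_inject", n_in=len(chunk), n_out=len(augmented))
        size = len(chunk) if cfg.bootstrap_size_rule == "original_size" else len(augmented)
        sample = bootstrap_sample(augmented, size, rng)
    else:
        sample = bootstrap_sample(chunk, len(chunk), rng)
    emit("bootstrap", n=len(sample))
    selected = sfs_select(sample.X, sample.labels, kind, cfg, rng)
    emit("sfs", selected=list(selected))
    model = fit_base(
        kind,
        sample.X[:, selected],
        sample.labels,
        origin=origin,
        selected_features=selected,
        n_features_total=chunk.n_features,
        options=cfg.classifier_options,
        random_state=int(rng.integers(2 ** 31 - 1)),
    )
    emit("fit", kind=kind, origin=origin)
    return model
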
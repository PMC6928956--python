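"""Per-window feature extraction for activity recognition.

Raw channels are first expanded into derived signals: for every (x, y, z)
sensor triad, the Euclidean magnitude sqrt(x²+y²+z²) and the three pairwise
magnitudes sqrt(a²+b²) — seven signals per triad.  From every derived signal
a fixed bank of 30 features is computed:

* std, min, max, median (4)
* percentiles 10, 25, 75, 90 (4)
* tail sums: sum of values below P10/P25 and above P75/P90 (4)
* the analogous tail square sums (4)
* level-crossing counts of each percentile, i.e. sign changes of
  (x_t − P_q) with zeros carrying the previous nonzero sign (4)
* band sums of the non-negative-frequency FFT magnitude spectrum, zero
  frequency excluded, split into ``n_freq_bands`` equal contiguous bins (10)

A 3-channel recording therefore yields 7 × 30 = 210 features per window.
Feature names and order are stable across runs.  No standardization is
applied here; scaling is the base learner's concern so feature semantics
stay fixed for the feature-selection wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .signal_io import Window

__all__ = [
    "FeatureConfig", "FeatureSet", "FeatureWindow",
    "derive_signals", "extract_features", "featurize",
    "feature_names_for_signal",
]


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-bank configuration.

    ``percentiles`` must be strictly increasing and inside (0, 100);
    percentiles below 50 contribute lower-tail sums, those above 50
    upper-tail sums.
    """

    percentiles: tuple[float, ...] = (10.0, 25.0, 75.0, 90.0)
    n_freq_bands: int = 10
    include_pairwise: bool = True
    include_magnitude: bool = True

    def __post_init__(self) -> None:
        p = np.asarray(self.percentiles, dtype=float)
        if p.size == 0 or np.any(p <= 0) or np.any(p >= 100) or np.any(np.diff(p) <= 0):
            raise ConfigError(
                "percentiles must be strictly increasing and inside (0, 100)"
            )
        if self.n_freq_bands < 1:
            raise ConfigError("n_freq_bands must be >= 1")


def feature_names_for_signal(cfg: FeatureConfig) -> list[str]:
    """Ordered names of the per-signal feature bank."""
    names = ["std", "min", "max", "median"]
    names += [f"p{q:g}" for q in cfg.percentiles]
    for q in cfg.percentiles:
        tail = "below" if q < 50 else "above"
        names.append(f"sum_{tail}_p{q:g}")
    for q in cfg.percentiles:
        tail = "below" if q < 50 else "above"
        names.append(f"sqsum_{tail}_p{q:g}")
    names += [f"crossings_p{q:g}" for q in cfg.percentiles]
    names += [f"fband_{i + 1:02d}" for i in range(cfg.n_freq_bands)]
    return names


def _crossing_counts(X: np.ndarray, levels: np.ndarray) -> np.ndarray:
    """Sign changes of (x_t - level) per row; zeros carry the previous
    nonzero sign, leading zeros carry no sign."""
    S = np.sign(X - levels[:, None]).astype(np.int8)
    n, L = S.shape
    pos = np.where(S != 0, np.arange(L)[None, :], -1)
    last = np.maximum.accumulate(pos, axis=1)
    filled = np.where(
        last >= 0,
        np.take_along_axis(S, np.maximum(last, 0), axis=1),
        0,
    )
    changed = (filled[:, 1:] != filled[:, :-1]) & (filled[:, :-1] != 0)
    return changed.sum(axis=1).astype(float)


def _feature_block(X: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    """Compute the 30-feature bank for a batch of signals (rows)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] < 2:
        raise DataError("signal length must be >= 2 for feature extraction")
    cols: list[np.ndarray] = [
        X.std(axis=1),
        X.min(axis=1),
        X.max(axis=1),
        np.median(X, axis=1),
    ]
    P = {q: np.percentile(X, q, axis=1) for q in cfg.percentiles}
    cols += [P[q] for q in cfg.percentiles]
    for q in cfg.percentiles:
        mask = (X < P[q][:, None]) if q < 50 else (X > P[q][:, None])
        cols.append((X * mask).sum(axis=1))
    for q in cfg.percentiles:
        mask = (X < P[q][:, None]) if q < 50 else (X > P[q][:, None])
        cols.append((X ** 2 * mask).sum(axis=1))
    for q in cfg.percentiles:
        cols.append(_crossing_counts(X, P[q]))
    spectrum = np.abs(np.fft.rfft(X, axis=1))[:, 1:]
    band_index = np.array_split(np.arange(spectrum.shape[1]), cfg.n_freq_bands)
    for idx in band_index:
        cols.append(spectrum[:, idx].sum(axis=1))
    return np.column_stack(cols)


def extract_features(signal, cfg: FeatureConfig | None = None) -> dict[str, float]:
    """Feature bank of a single derived signal as an ordered name -> value map."""
    cfg = cfg or FeatureConfig()
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DataError("signal contains non-finite values")
    values = _feature_block(x, cfg)[0]
    return dict(zip(feature_names_for_signal(cfg), values))


def derive_signals(
    signals: dict[str, np.ndarray],
    include_magnitude: bool = True,
    include_pairwise: bool = True,
) -> dict[str, np.ndarray]:
    """Expand raw channels with triad magnitude and pairwise-magnitude signals.

    Channels are grouped into (x, y, z) triads by their order; per triad the
    output is ``a, b, c, mag(a,b,c), mag(a,b), mag(a,c), mag(b,c)``.  Arrays
    may be 1-D signals or 2-D batches (rows = windows).
    """
    names = list(signals)
    if (include_magnitude or include_pairwise) and len(names) % 3 != 0:
        raise ConfigError(
            f"channel count {len(names)} is not a multiple of 3; "
            "triad-derived signals need (x, y, z) groups"
        )
    out: dict[str, np.ndarray] = {}
    if not (include_magnitude or include_pairwise):
        return {n: np.asarray(signals[n], dtype=float) for n in names}
    for i in range(0, len(names), 3):
        a, b, c = names[i:i + 3]
        xa, xb, xc = (np.asarray(signals[k], dtype=float) for k in (a, b, c))
        out[a], out[b], out[c] = xa, xb, xc
        if include_magnitude:
            out[f"mag({a},{b},{c})"] = np.sqrt(xa ** 2 + xb ** 2 + xc ** 2)
        if include_pairwise:
            out[f"mag({a},{b})"] = np.sqrt(xa ** 2 + xb ** 2)
            out[f"mag({a},{c})"] = np.sqrt(xa ** 2 + xc ** 2)
            out[f"mag({b},{c})"] = np.sqrt(xb ** 2 + xc ** 2)
    return out


@dataclass
class FeatureWindow:
    """One window's feature vector with provenance (lightweight view)."""

    subject_id: str
    index: int
    feature_vector: np.ndarray
    feature_names: list[str]
    label: str


@dataclass
class FeatureSet:
    """Columnar, stream-ordered collection of feature windows.

    ``w`` holds the stream-order window indices (strictly increasing within
    a subject), ``X`` the (n, p) feature matrix and ``labels`` the per-window
    class labels.
    """

    subject_ids: np.ndarray
    w: np.ndarray
    X: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.w = np.asarray(self.w, dtype=int)
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        n = len(self.labels)
        if not (len(self.subject_ids) == len(self.w) == self.X.shape[0] == n):
            raise DataError("FeatureSet columns have inconsistent lengths")
        if self.feature_names and len(self.feature_names) != self.X.shape[1]:
            raise DataError("feature_names length != feature dimension")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def class_set(self) -> list[str]:
        return sorted(set(self.labels.tolist()))

    def windows(self):
        """Iterate rows as :class:`FeatureWindow` views."""
        for i in range(len(self)):
            yield FeatureWindow(
                subject_id=self.subject_ids[i],
                index=int(self.w[i]),
                feature_vector=self.X[i],
                feature_names=self.feature_names,
                label=self.labels[i],
            )

    def select(self, idx) -> "FeatureSet":
        """Row subset / reorder (bootstrap draws keep their w indices)."""
        return FeatureSet(
            subject_ids=self.subject_ids[idx],
            w=self.w[idx],
            X=self.X[idx],
            labels=self.labels[idx],
            feature_names=self.feature_names,
        )

    def with_labels(self, labels) -> "FeatureSet":
        """Copy with the label column replaced (used after chunk labeling)."""
        return FeatureSet(
            subject_ids=self.subject_ids,
            w=self.w,
            X=self.X,
            labels=np.asarray(labels, dtype=object),
            feature_names=self.feature_names,
        )

    @classmethod
    def concat(cls, parts: list["FeatureSet"]) -> "FeatureSet":
        if not parts:
            raise DataError("cannot concatenate zero FeatureSets")
        names = parts[0].feature_names
        for p in parts[1:]:
            if p.feature_names != names:
                raise DataError("FeatureSets have different feature names")
        return cls(
            subject_ids=np.concatenate([p.subject_ids for p in parts]),
            w=np.concatenate([p.w for p in parts]),
            X=np.vstack([p.X for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            feature_names=names,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "w", self.w)
        df.insert(0, "subject_id", self.subject_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureSet":
        meta = ["subject_id", "w", "label"]
        names = [c for c in df.columns if c not in meta]
        return cls(
            subject_ids=df["subject_id"].to_numpy(dtype=object),
            w=df["w"].to_numpy(dtype=int),
            X=df[names].to_numpy(dtype=float),
            labels=df["label"].to_numpy(dtype=object),
            feature_names=names,
        )

    @classmethod
    def from_csv(cls, path) -> "FeatureSet":
        return cls.from_frame(pd.read_csv(path))


def featurize(windows: list[Window], cfg: FeatureConfig | None = None) -> FeatureSet:
    """Compute the full feature bank for a list of windows.

    All windows must share one channel set.  Raises :class:`DataError` if a
    window produces non-finite feature values.
    """
    cfg = cfg or FeatureConfig()
    if not windows:
        raise DataError("featurize: empty window list")
    channel_names = windows[0].channel_names
    for win in windows:
        if win.channel_names != channel_names:
            raise DataError("featurize: inconsistent channel sets across windows")
    stacked = np.stack([win.samples for win in windows], axis=0)  # (n, C, W)
    signals = {name: stacked[:, i, :] for i, name in enumerate(channel_names)}
    derived = derive_signals(
        signals,
        include_magnitude=cfg.include_magnitude,
        include_pairwise=cfg.include_pairwise,
    )
    per_signal = feature_names_for_signal(cfg)
    blocks, names = [], []
    for sig_name, batch in derived.items():
        blocks.append(_feature_block(batch, cfg))
        names += [f"{sig_name}.{f}" for f in per_signal]
    X = np.hstack(blocks)
    bad = ~np.isfinite(X).all(axis=1)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise DataError(
            f"non-finite feature values in window w={windows[i].index} "
            f"(subject {windows[i].subject_id})"
        )
    return FeatureSet(
        subject_ids=np.array([win.subject_id for win in windows], dtype=object),
        w=np.array([win.index for win in windows], dtype=int),
        X=X,
        labels=np.array([win.label for win in windows], dtype=object),
        feature_names=names,
    )
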
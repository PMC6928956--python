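"""Chunk-labeling policies: non-supervised, semi-supervised, supervised.

The semi-supervised policy is the interesting one: the ensemble predicts
every window of an incoming chunk, windows whose confidence falls strictly
below a threshold are queried from the user (the oracle), and — because
activities are long-bout — each queried window's true label is propagated to
its in-chunk neighbours within ±2 windows.  The threshold is 0.95 while the
ensemble contains only user-independent members and drops to 0.75 once any
personal member has been added, balancing query load between update rounds.

Propagated labels count as "replaced" labels but not as user inputs, so the
fraction of replaced labels always bounds the query fraction from above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, LabelingError
from .features import FeatureSet
from .learnpp import EnsembleModel

Mode = Literal["non_supervised", "semi_supervised", "supervised"]

#: Window-label provenance markers.
PREDICTED, QUERIED, PROPAGATED = "predicted", "queried", "propagated"


@dataclass(frozen=True)
class LabelingPolicy:
    """How an unlabeled personal chunk obtains its labels.

    ``th_ui`` applies while the ensemble has no personal member, and
    ``th_personal`` afterwards.  Thresholds may reach 1.01: since confidences
    are <= 1 and the query condition is a strict "<", a threshold above 1
    queries every window, reproducing the supervised policy; thresholds of 0
    query nothing, reproducing the non-supervised policy.
    """

    mode: Mode = "semi_supervised"
    th_ui: float = 0.95
    th_personal: float = 0.75
    propagation_radius: int = 2

    def __post_init__(self) -> None:
        if self.mode not in ("non_supervised", "semi_supervised", "supervised"):
            raise ConfigError(f"mode: unknown labeling mode {self.mode!r}")
        for name in ("th_ui", "th_personal"):
            if not 0 <= getattr(self, name) <= 1.01:
                raise ConfigError(f"{name} must lie in [0, 1.01]")
        if self.propagation_radius < 0:
            raise ConfigError("propagation_radius must be >= 0")


class Oracle:
    """Ground-truth label source, deterministic per (subject, window index)."""

    def __init__(self, lookup: Callable[[str, int], str]) -> None:
        self._lookup = lookup

    def __call__(self, subject_id: str, w: int) -> str:
        return self._lookup(subject_id, w)

    @classmethod
    def from_feature_set(cls, fs: FeatureSet) -> "Oracle":
        """Oracle backed by a feature set's own (true) labels."""
        table = {
            (str(s), int(i)): str(lab)
            for s, i, lab in zip(fs.subject_ids, fs.w, fs.labels)
        }

        def lookup(subject_id: str, w: int) -> str:
            try:
                return table[(str(subject_id), int(w))]
            except KeyError:
                raise LabelingError(
                    f"oracle has no label for (subject {subject_id}, w={w})"
                ) from None

        return cls(lookup)


@dataclass
class LabeledChunk:
    """A chunk with assigned labels and per-window provenance."""

    features: FeatureSet
    assigned_labels: np.ndarray
    source: np.ndarray  # entries in {predicted, queried, propagated}
    threshold: float | None = None
    round_index: int | None = None

    def __post_init__(self) -> None:
        self.assigned_labels = np.asarray(self.assigned_labels, dtype=object)
        self.source = np.asarray(self.source, dtype=object)
        n = len(self.features)
        if len(self.assigned_labels) != n or len(self.source) != n:
            raise DataError("labels/source length mismatch with chunk")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def query_fraction(self) -> float:
        return float(np.mean(self.source == QUERIED))

    @property
    def replaced_fraction(self) -> float:
        return float(np.mean(self.source != PREDICTED))

    def labeled_features(self) -> FeatureSet:
        """The chunk with assigned labels substituted for training."""
        return self.features.with_labels(self.assigned_labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "w": self.features.w,
            "assigned_label": self.assigned_labels,
            "source": self.source,
        })


def select_threshold(ens: EnsembleModel, pol: LabelingPolicy) -> float:
    """The posterior threshold the semi-supervised policy applies now."""
    if pol.mode != "semi_supervised":
        raise ConfigError("select_threshold applies only to semi_supervised mode")
    return pol.th_personal if ens.has_personal() else pol.th_ui


def _propagate(positions_queried: np.ndarray, n: int, radius: int) -> np.ndarray:
    """For each position, the queried source position whose label it receives
    by propagation, or -1.  Nearest queried window wins; distance ties go to
    the earlier (smaller-position) queried window; queried positions keep
    themselves."""
    source = np.full(n, -1, dtype=int)
    best_dist = np.full(n, np.iinfo(int).max)
    for q in positions_queried:  # ascending, so ties keep the earlier q
        lo, hi = max(0, q - radius), min(n - 1, q + radius)
        for j in range(lo, hi + 1):
            dist = abs(j - q)
            if dist < best_dist[j]:
                best_dist[j] = dist
                source[j] = q
    return source


def label_chunk(
    ens: EnsembleModel,
    chunk: FeatureSet,
    pol: LabelingPolicy,
    oracle: Oracle,
    round_index: int | None = None,
) -> LabeledChunk:
    """Label a personal chunk under the policy.

    Windows are treated as consecutive in stream order; propagation never
    crosses the chunk boundary.  Queried windows always carry the oracle
    label and are never overwritten by propagation.
    """
    n = len(chunk)
    if n == 0:
        raise DataError("label_chunk: empty chunk")
    if pol.mode == "supervised":
        labels = np.array(
            [oracle(s, w) for s, w in zip(chunk.subject_ids, chunk.w)],
            dtype=object,
        )
        return LabeledChunk(chunk, labels, np.repeat(QUERIED, n),
                            threshold=None, round_index=round_index)

    preds = ens.predict_batch(chunk)
    labels = np.array([p.label for p in preds], dtype=object)
    source = np.repeat(PREDICTED, n).astype(object)
    if pol.mode == "non_supervised":
        return LabeledChunk(chunk, labels, source,
                            threshold=None, round_index=round_index)

    th = select_threshold(ens, pol)
    conf = np.array([p.confidence for p in preds])
    queried_pos = np.flatnonzero(conf < th)
    oracle_labels = {
        int(q): oracle(chunk.subject_ids[q], int(chunk.w[q])) for q in queried_pos
    }
    for q, lab in oracle_labels.items():
        labels[q] = lab
        source[q] = QUERIED
    if pol.propagation_radius > 0 and queried_pos.size:
        prop_source = _propagate(queried_pos, n, pol.propagation_radius)
        for j in range(n):
            if source[j] != QUERIED and prop_source[j] >= 0:
                labels[j] = oracle_labels[int(prop_source[j])]
                source[j] = PROPAGATED
    return LabeledChunk(chunk, labels, source, threshold=th,
                        round_index=round_index)


def summarize_queries(chunks: list[LabeledChunk]) -> pd.DataFrame:
    """Per-round and overall mean query/replaced fractions.

    Chunks must carry a ``round_index``; the overall row averages the
    per-chunk fractions.
    """
    rows = [
        {"round": c.round_index, "query_fraction": c.query_fraction,
         "replaced_fraction": c.replaced_fraction}
        for c in chunks
    ]
    df = pd.DataFrame(rows)
    per_round = df.groupby("round", dropna=False).mean().reset_index()
    overall = pd.DataFrame([{
        "round": "overall",
        "query_fraction": df["query_fraction"].mean(),
        "replaced_fraction": df["replaced_fraction"].mean(),
    }])
    return pd.concat([per_round, overall], ignore_index=True)
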
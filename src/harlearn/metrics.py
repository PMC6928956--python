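"""Evaluation metrics: balanced accuracy and macro false-negative rate.

Balanced accuracy is the unweighted mean of per-class recalls over the
classes present in ``y_true`` — the right choice for imbalanced activity
data.  The macro false-negative rate is the mean of (1 − recall) over the
same classes, hence identically 1 − balanced accuracy.
"""

from __future__ import annotations

import numpy as np

from .errors import DataError


def _recalls(y_true, y_pred) -> np.ndarray:
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise DataError("y_true and y_pred must be non-empty and equal-length")
    classes = np.unique(y_true)
    return np.array([np.mean(y_pred[y_true == c] == c) for c in classes])


def balanced_accuracy(y_true, y_pred) -> float:
    """Mean per-class recall over the classes present in ``y_true``."""
    return float(_recalls(y_true, y_pred).mean())


def error_rate(y_true, y_pred) -> float:
    """1 − balanced accuracy."""
    return 1.0 - balanced_accuracy(y_true, y_pred)


def macro_fnr(y_true, y_pred) -> float:
    """Mean per-class false-negative rate (= 1 − balanced accuracy)."""
    return float((1.0 - _recalls(y_true, y_pred)).mean())
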
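"""Reading, writing and windowing of labeled multi-channel sensor recordings.

A recording is a per-sample labeled stream from one subject (e.g. a 3-axis
accelerometer at 50 Hz).  Recordings are exchanged as plain CSV with a
``timestamp`` column, one column per channel, a ``label`` column and an
optional ``subject_id`` column.  :func:`segment_windows` cuts a recording into
fixed-length, overlapping windows — the unit of classification throughout the
package.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError

logger = logging.getLogger(__name__)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class RawRecording:
    """One subject's multi-channel labeled sensor stream.

    Parameters
    ----------
    subject_id : str
        Identifier of the wearer.
    sampling_rate_hz : float
        Sampling frequency; strictly positive.
    channels : dict of str -> ndarray
        Named, ordered, equal-length real-valued sample sequences.
    labels : ndarray of str
        Per-sample activity label, same length as every channel.
    """

    subject_id: str
    sampling_rate_hz: float
    channels: dict[str, np.ndarray]
    labels: np.ndarray

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ConfigError("sampling_rate_hz must be > 0")
        if len(self.channels) < 1:
            raise ConfigError("channels: at least one channel required")
        self.labels = np.asarray(self.labels, dtype=object)
        n = len(self.labels)
        for name, values in self.channels.items():
            arr = np.asarray(values, dtype=float)
            if arr.ndim != 1 or len(arr) != n:
                raise ConfigError(
                    f"channels[{name!r}]: length {len(arr)} != label length {n}"
                )
            self.channels[name] = arr

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def channel_matrix(self) -> np.ndarray:
        """Channels stacked as a (n_channels, n_samples) array."""
        return np.stack([self.channels[c] for c in self.channels], axis=0)

    def slice(self, start: int, stop: int, subject_id: str | None = None) -> "RawRecording":
        """Sub-recording over the half-open sample interval [start, stop)."""
        return RawRecording(
            subject_id=subject_id if subject_id is not None else self.subject_id,
            sampling_rate_hz=self.sampling_rate_hz,
            channels={c: v[start:stop].copy() for c, v in self.channels.items()},
            labels=self.labels[start:stop].copy(),
        )


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry.

    ``window_seconds`` and ``slide_seconds`` are converted to sample counts
    with round-half-up; a 1/3 s slide at 50 Hz therefore becomes 17 samples.
    Windows whose modal-label purity falls below ``min_purity`` are dropped.
    """

    window_seconds: float = 4.2
    slide_seconds: float = 1.4
    min_purity: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.slide_seconds <= self.window_seconds:
            raise ConfigError(
                "slide_seconds must satisfy 0 < slide_seconds <= window_seconds"
            )
        if not 0 <= self.min_purity <= 1:
            raise ConfigError("min_purity must lie in [0, 1]")

    def window_samples(self, sampling_rate_hz: float) -> int:
        return _round_half_up(self.window_seconds * sampling_rate_hz)

    def slide_samples(self, sampling_rate_hz: float) -> int:
        return max(1, _round_half_up(self.slide_seconds * sampling_rate_hz))


@dataclass
class Window:
    """A fixed-length slice of a recording with its majority label.

    ``start_sample``/``end_sample`` form a 0-based half-open interval;
    ``index`` is the window's position in stream order (consecutive among
    retained windows).  ``purity`` is the fraction of samples carrying the
    majority label; ties are broken by first occurrence within the window.
    """

    subject_id: str
    index: int
    start_sample: int
    end_sample: int
    samples: np.ndarray  # (n_channels, window_samples)
    channel_names: list[str]
    label: str
    purity: float = field(default=1.0)


def _modal_label(labels: np.ndarray) -> tuple[str, float]:
    counts = Counter(labels.tolist())  # Counter preserves first-occurrence order
    label, count = counts.most_common(1)[0]
    return label, count / len(labels)


def segment_windows(rec: RawRecording, spec: WindowSpec) -> list[Window]:
    """Cut a recording into overlapping fixed-length windows.

    Window starts are 0, d, 2d, ... with d the slide in samples; the count is
    floor((L - W) / d) + 1.  Each window's label is the per-sample modal
    label; windows whose purity is below ``spec.min_purity`` are dropped and
    the survivors are renumbered with consecutive stream-order indices.

    A recording shorter than one window yields an empty list (with a logged
    warning), not an error.
    """
    W = spec.window_samples(rec.sampling_rate_hz)
    d = spec.slide_samples(rec.sampling_rate_hz)
    L = rec.n_samples
    if L < W:
        logger.warning(
            "recording %s (%d samples) shorter than one window (%d samples)",
            rec.subject_id, L, W,
        )
        return []
    mat = rec.channel_matrix()
    names = rec.channel_names
    windows: list[Window] = []
    idx = 0
    for start in range(0, L - W + 1, d):
        end = start + W
        label, purity = _modal_label(rec.labels[start:end])
        if purity < spec.min_purity:
            continue
        windows.append(Window(
            subject_id=rec.subject_id,
            index=idx,
            start_sample=start,
            end_sample=end,
            samples=mat[:, start:end],
            channel_names=names,
            label=label,
            purity=purity,
        ))
        idx += 1
    return windows


def read_recording(
    path,
    channel_columns: list[str],
    sampling_rate_hz: float | None = None,
    subject_id: str | None = None,
) -> RawRecording:
    """Read a labeled recording from CSV.

    The file must have a header with ``timestamp``, the named channel columns
    and ``label`` (plus an optional ``subject_id`` column).  The sampling rate
    is taken from ``sampling_rate_hz`` when given, otherwise inferred as the
    reciprocal of the median timestamp spacing.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    required = ["timestamp", *channel_columns, "label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    ts = df["timestamp"].to_numpy(dtype=float)
    if len(ts) > 1:
        dt = np.diff(ts)
        if np.any(dt <= 0):
            raise FormatError(f"{path}: timestamps not strictly increasing")
        if sampling_rate_hz is None:
            sampling_rate_hz = 1.0 / float(np.median(dt))
    elif sampling_rate_hz is None:
        raise FormatError(f"{path}: cannot infer sampling rate from one row")
    if subject_id is None:
        if "subject_id" in df.columns:
            subject_id = str(df["subject_id"].iloc[0])
        else:
            subject_id = "unknown"
    return RawRecording(
        subject_id=subject_id,
        sampling_rate_hz=float(sampling_rate_hz),
        channels={c: df[c].to_numpy(dtype=float) for c in channel_columns},
        labels=df["label"].to_numpy(dtype=object),
    )


def write_recording(rec: RawRecording, path) -> None:
    """Write a recording as CSV (inverse of :func:`read_recording`)."""
    n = rec.n_samples
    data = {"timestamp": np.arange(n) / rec.sampling_rate_hz}
    for c in rec.channel_names:
        data[c] = rec.channels[c]
    data["label"] = rec.labels
    data["subject_id"] = np.repeat(rec.subject_id, n)
    pd.DataFrame(data).to_csv(path, index=False)
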
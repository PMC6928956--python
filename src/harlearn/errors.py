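"""Exception hierarchy for harlearn.

All validation failures raise a subclass of :class:`HarlearnError` so callers
can distinguish configuration mistakes from malformed data or failed training.
"""


class HarlearnError(Exception):
    """Base class for all harlearn errors."""


class ConfigError(HarlearnError, ValueError):
    """Invalid configuration value; the message names the offending field."""


class FormatError(HarlearnError, ValueError):
    """Malformed input file (missing columns, bad timestamps, empty file)."""


class DataError(HarlearnError, ValueError):
    """Data violates an operation's contract (non-finite values, mismatched
    channel sets, dimension mismatch)."""


class TrainingError(HarlearnError, RuntimeError):
    """A model could not be trained (degenerate labels, too few samples)."""


class LabelingError(HarlearnError, RuntimeError):
    """The labeling oracle failed for a queried window."""


class ProtocolError(HarlearnError, RuntimeError):
    """The experimental protocol cannot be applied (e.g. an activity block is
    too short to split into three window-bearing parts)."""
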
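"""Seeded generator of multi-subject, multi-class inertial sensor streams.

Each activity class has a sinusoidal base signature on three axes
(amplitude · sin(2π·f·t + axis phase) + per-axis offset, axis phases fixed at
0, 2π/3 and 4π/3).  Every subject perturbs every class's signature with its
own multiplicative gain, additive per-axis offset and frequency factor, drawn
once per (subject, class); white Gaussian noise is added per sample.  The
subject-level perturbations create a real, learnable between-subject shift:
a recognizer trained on other subjects is systematically worse on a new
subject than one trained on that subject's own data, which is the premise
personalization exploits.

Randomness is keyed per subject from ``(seed, subject index)`` so a cohort is
bit-reproducible regardless of subject iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .signal_io import RawRecording

#: Default per-class sinusoid parameters: (amplitude, frequency Hz,
#: per-axis mean offsets).  Classes deliberately pair up on frequency
#: (still/walk at 1 Hz, run/bike at 2 Hz) and differ in amplitude and
#: offsets, so subject-level gain/offset shifts make classes confusable
#: across subjects while staying separable within one subject.
DEFAULT_CLASS_PARAMS: dict[str, tuple[float, float, tuple[float, float, float]]] = {
    "still": (0.4, 1.0, (0.0, 0.3, -0.3)),
    "walk": (0.9, 1.0, (0.3, 0.0, 0.0)),
    "run": (0.9, 2.0, (0.0, -0.3, 0.3)),
    "bike": (1.4, 2.0, (-0.3, 0.0, 0.3)),
    "stairs": (1.4, 3.0, (0.3, 0.3, 0.0)),
}

_AXIS_PHASES = np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3])
_CHANNEL_NAMES = ["acc_x", "acc_y", "acc_z"]


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic cohort.

    Parameters
    ----------
    n_subjects : int
        Number of subjects (>= 2).
    class_params : dict
        ``{class_name: (amplitude, frequency_hz, (off_x, off_y, off_z))}``.
    sampling_rate_hz : float
        Sensor sampling frequency (default 50 Hz).
    seconds_per_class : float
        Length of each subject's contiguous block per class (default 120 s),
        giving equal amounts of data from each activity.
    subject_gain_sd : float
        SD of the per-(subject, class) multiplicative gain around 1.
    subject_offset_sd : float
        SD of the per-(subject, class, axis) additive offset, signal units.
    subject_freq_sd : float
        SD of the per-(subject, class) frequency factor around 1.
    noise_sd : float
        SD of the iid per-sample Gaussian noise, signal units.
    seed : int
        Base seed; identical config + seed gives bit-identical cohorts.
    """

    n_subjects: int = 8
    class_params: dict[str, tuple[float, float, tuple[float, float, float]]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PARAMS)
    )
    sampling_rate_hz: float = 50.0
    seconds_per_class: float = 120.0
    subject_gain_sd: float = 0.15
    subject_offset_sd: float = 0.3
    subject_freq_sd: float = 0.05
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        if len(self.class_params) < 2:
            raise ConfigError("class_params must define >= 2 classes")
        if self.sampling_rate_hz <= 0:
            raise ConfigError("sampling_rate_hz must be > 0")
        if self.seconds_per_class <= 0:
            raise ConfigError("seconds_per_class must be > 0")
        for name in ("subject_gain_sd", "subject_offset_sd",
                     "subject_freq_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")

    @property
    def class_names(self) -> list[str]:
        return list(self.class_params)

    @property
    def samples_per_class(self) -> int:
        return int(round(self.seconds_per_class * self.sampling_rate_hz))


def generate_recording(config: SyntheticConfig, subject_index: int) -> RawRecording:
    """Generate one subject's stream: one contiguous labeled block per class.

    The subject's random stream is derived from ``(config.seed,
    subject_index)`` only, so subjects are independent and reproducible.
    """
    rng = np.random.default_rng([config.seed, subject_index])
    n = config.samples_per_class
    t = np.arange(n) / config.sampling_rate_hz
    segments = []
    labels = []
    for cls, (amp, freq, offsets) in config.class_params.items():
        gain = rng.normal(1.0, config.subject_gain_sd)
        offset = rng.normal(0.0, config.subject_offset_sd, size=3)
        freq_factor = rng.normal(1.0, config.subject_freq_sd)
        base = (
            gain * amp * np.sin(
                2 * np.pi * freq * freq_factor * t[None, :] + _AXIS_PHASES[:, None]
            )
            + np.asarray(offsets)[:, None]
            + offset[:, None]
        )
        noise = rng.normal(0.0, config.noise_sd, size=base.shape)
        segments.append(base + noise)
        labels.append(np.repeat(cls, n))
    signal = np.concatenate(segments, axis=1)
    return RawRecording(
        subject_id=f"S{subject_index:02d}",
        sampling_rate_hz=config.sampling_rate_hz,
        channels={name: signal[i] for i, name in enumerate(_CHANNEL_NAMES)},
        labels=np.concatenate(labels),
    )


def generate_cohort(config: SyntheticConfig) -> list[RawRecording]:
    """Generate one :class:`RawRecording` per subject."""
    return [generate_recording(config, i) for i in range(config.n_subjects)]
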
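"""YAML experiment configuration.

A config file may define any of the sections ``synthetic``, ``window``,
``features``, ``train``, ``policy`` and ``experiment``; omitted fields fall
back to the package defaults documented on each dataclass.
"""

from __future__ import annotations

import yaml

from .errors import ConfigError
from .features import FeatureConfig
from .labeling import LabelingPolicy
from .pipeline import ExperimentConfig
from .signal_io import WindowSpec
from .synthetic_data import SyntheticConfig
from .training import TrainConfig


def _build(cls, section: dict, name: str):
    try:
        return cls(**section)
    except TypeError as exc:
        raise ConfigError(f"section {name!r}: {exc}") from None


def load_config(path) -> dict:
    """Load a YAML config into the package's configuration objects.

    Returns ``{"synthetic": SyntheticConfig, "experiment": ExperimentConfig}``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    synth_raw = dict(raw.get("synthetic", {}))
    if "class_params" in synth_raw:
        synth_raw["class_params"] = {
            str(k): (float(v[0]), float(v[1]), tuple(float(x) for x in v[2]))
            for k, v in synth_raw["class_params"].items()
        }
    synthetic = _build(SyntheticConfig, synth_raw, "synthetic")
    window = _build(WindowSpec, dict(raw.get("window", {})), "window")
    features_raw = dict(raw.get("features", {}))
    if "percentiles" in features_raw:
        features_raw["percentiles"] = tuple(features_raw["percentiles"])
    features = _build(FeatureConfig, features_raw, "features")
    train = _build(TrainConfig, dict(raw.get("train", {})), "train")
    policy = _build(LabelingPolicy, dict(raw.get("policy", {})), "policy")
    exp_raw = dict(raw.get("experiment", {}))
    if "part_order" in exp_raw:
        exp_raw["part_order"] = tuple(exp_raw["part_order"])
    experiment = ExperimentConfig(
        policy=policy, window=window, features=features, train=train, **exp_raw
    )
    return {"synthetic": synthetic, "experiment": experiment}
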
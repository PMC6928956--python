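import numpy as np
import pytest

from harlearn import (
    FeatureConfig,
    SyntheticConfig,
    WindowSpec,
    generate_cohort,
    prepare_cohort,
)

TINY_SYNTH = dict(n_subjects=3, seconds_per_class=30.0, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Three subjects, 30 s per class: enough for 5 windows per part per class."""
    return generate_cohort(SyntheticConfig(**TINY_SYNTH))


@pytest.fixture(scope="session")
def tiny_features(tiny_cohort):
    return prepare_cohort(tiny_cohort, WindowSpec(), FeatureConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
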
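import warnings

import pytest
from hypothesis import HealthCheck, settings

from mammorisk import (
    GeneratorConfig,
    default_specs,
    encode_features,
    generate_cohort,
    train_classifier,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def specs():
    """The three bundled rule bases, loaded once."""
    return default_specs()


@pytest.fixture(scope="session")
def strong_cohort():
    """Default study conditions: 130 patients, 21 cancers, strong coupling."""
    return generate_cohort(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def strong_model(strong_cohort):
    """Classifier trained once on the strong-signal cohort."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return train_classifier(encode_features(strong_cohort), seed=7)
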
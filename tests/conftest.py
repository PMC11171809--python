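import numpy as np
import pytest

from cardiolos.evaluation import prepare_modeling_data
from cardiolos.feature_engineering import build_feature_table
from cardiolos.synthetic_cohort import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """~550 training encounters; shared across test modules."""
    return generate_cohort(GeneratorConfig(n_patients=1000, seed=7))


@pytest.fixture(scope="session")
def feature_data(small_cohort):
    features, metadata = build_feature_table(small_cohort)
    return features, metadata


@pytest.fixture(scope="session")
def model_data(feature_data):
    """Encoded matrix, scaled log target, class bundle, registry, fitted
    preprocessor."""
    features, metadata = feature_data
    return prepare_modeling_data(features, metadata)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
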
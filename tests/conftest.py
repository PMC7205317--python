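import numpy as np
import pytest

from polya_rhythms import Variant, sample_lhs, global_spec
from polya_rhythms.batch import sweep_features


@pytest.fixture(scope="session")
def global_sweep_small():
    """2,000-set global-distribution sweep of the full model, shared across tests."""
    theta = sample_lhs(global_spec(Variant.FULL), 2000, 20240115)
    return sweep_features(theta)


@pytest.fixture(scope="session")
def global_sweep_10k():
    """10,000-set global-distribution sweep used by the phase-lag acceptance checks."""
    theta = sample_lhs(global_spec(Variant.FULL), 10_000, 917)
    return sweep_features(theta)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
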
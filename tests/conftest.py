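import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def locus():
    """One toy locus instance shared by structural tests."""
    from poolscan import simdata as sd

    cfg = sd.LocusSimConfig(seed=42)
    records, truth = sd.simulate_locus_sequences(cfg)
    return cfg, records, truth
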
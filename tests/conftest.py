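import numpy as np
import pytest

from plskrige import ScenarioConfig, generate_study


@pytest.fixture(scope="session")
def small_study():
    """A small S-like synthetic study shared across read-only tests."""
    cfg = ScenarioConfig.s_like(n_monitors=60, n_subjects=80, seed=7)
    return generate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
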
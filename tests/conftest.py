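import numpy as np
import pytest

from poolgen import synthetic_data as sd


@pytest.fixture(scope="session")
def small_dataset():
    """A small clean multi-study dataset shared across read-only tests."""
    cfg = sd.SimConfig(n_studies=4, cases_per_study=150, controls_per_study=200,
                       seed=11)
    return sd.generate_multistudy(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
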
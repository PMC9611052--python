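import numpy as np
import pytest

from micellekit import CopolymerSpec, InjectionSchedule, SiRNASpec
from micellekit.synthetic import GeneratorConfig


@pytest.fixture
def copolymer():
    return CopolymerSpec()


@pytest.fixture
def sirna():
    return SiRNASpec()


@pytest.fixture
def schedule():
    return InjectionSchedule()


@pytest.fixture
def quiet_cfg():
    """Noise-free generator configuration for exact round trips."""
    return GeneratorConfig(seed=0, itc_noise_fraction=0.0, itc_drift=0.0,
                           series_sigma=0.0, cze_noise_mau=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
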
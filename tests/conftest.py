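import numpy as np
import pytest

from betazip.exchange_core import CestExperiment, CpmgExperiment, ExchangeModel


@pytest.fixture
def two_state_model():
    return ExchangeModel((0.89, 0.11), kex_ab=104.0, dw_ab_ppm=2.0,
                         r1=1.2, r2=10.0)


@pytest.fixture
def three_state_model():
    return ExchangeModel((0.84, 0.11, 0.05), kex_ab=104.0, dw_ab_ppm=2.0,
                         kex_ac=2600.0, dw_ac_ppm=2.0, r1=1.2, r2=10.0)


@pytest.fixture
def cest_experiment():
    return CestExperiment.default_grid()


@pytest.fixture
def cpmg_experiment():
    return CpmgExperiment()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
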
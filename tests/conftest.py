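import numpy as np
import pytest

from deadwoodnet import presets, synth


@pytest.fixture(scope="session")
def default_landscape():
    return synth.generate_landscape(presets.default_landscape_config(), seed=1)


@pytest.fixture(scope="session")
def default_outcomes(default_landscape):
    return synth.generate_regime_outcomes(default_landscape, n_regimes=8, seed=2)


@pytest.fixture(scope="session")
def default_instance():
    return presets.default_instance(seed=1)


@pytest.fixture(scope="session")
def small_instance():
    return presets.small_instance(seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
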
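import numpy as np
import pytest

from metstab import load_wheat_fixture, fit_ammi, fit_gge


@pytest.fixture(scope="session")
def wheat():
    return load_wheat_fixture()


@pytest.fixture(scope="session")
def wheat_ammi(wheat):
    return fit_ammi(wheat.means, reps=wheat.replicates)


@pytest.fixture(scope="session")
def wheat_gge(wheat):
    return fit_gge(wheat.means)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
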
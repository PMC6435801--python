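import numpy as np
import pytest

from pmfdecomp.fixtures import harmonic_dumbbell
from pmfdecomp.model import SolventModel
from pmfdecomp.sampler import SamplingProtocol


@pytest.fixture
def dumbbell():
    return harmonic_dumbbell()


@pytest.fixture
def charged_dumbbell():
    return harmonic_dumbbell(charges=(0.5, -0.5))


@pytest.fixture
def vacuum():
    return SolventModel(eps_r=1.0, sa_on=False)


@pytest.fixture
def water_no_sa():
    return SolventModel(eps_r=80.0, sa_on=False)


@pytest.fixture
def quick_protocol():
    return SamplingProtocol(n_equilibration=200, n_production=1000, stride=2, seed=13)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
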
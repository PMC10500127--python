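import numpy as np
import pytest

from lfpshot import GammaIntervalSpec, events_to_pulse, sample_gamma_train

FS = 1000.0


@pytest.fixture(scope="session")
def poisson40_train():
    """A 300 s Poisson train at 40 Hz, shared across tests."""
    return sample_gamma_train(GammaIntervalSpec(1.0, 40.0), 300.0, seed=101)


@pytest.fixture(scope="session")
def regular40_train():
    """A 300 s strongly regular (a = 10^1.5) train at 40 Hz."""
    return sample_gamma_train(GammaIntervalSpec(10**1.5, 40.0), 300.0, seed=102)


@pytest.fixture(scope="session")
def poisson40_pulse(poisson40_train):
    return events_to_pulse(poisson40_train, FS)


@pytest.fixture(scope="session")
def regular40_pulse(regular40_train):
    return events_to_pulse(regular40_train, FS)
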
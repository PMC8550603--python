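import numpy as np
import pytest

from regtex import (SimulatedObserver, enumerate_pairs, simulate_observer,
                    synthetic_observer_means)
from regtex.conditions import N_CONDITIONS
from regtex.wavelets import LogGaborBank


@pytest.fixture(scope="session")
def pairs45():
    return enumerate_pairs(N_CONDITIONS)


@pytest.fixture(scope="session")
def synthetic_table(pairs45):
    """4-repetition response table of the default synthetic observer."""
    obs = SimulatedObserver(condition_means=synthetic_observer_means())
    return simulate_observer(obs, pairs45, 4, seed=7)


@pytest.fixture(scope="session")
def bank():
    """Default 256-pixel log-Gabor bank, shared across wavelet tests."""
    return LogGaborBank()
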
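import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

import spikeinfo as si


@pytest.fixture(scope="session")
def slow_regime():
    return si.get_regime("S")


@pytest.fixture(scope="session")
def frozen_slow_input(slow_regime):
    """A frozen 20 s slow-regime input (N = 400 presynaptic neurons)."""
    hidden, pop, trace = si.generate_regime_input(
        slow_regime, N=400, duration=20.0, seed=np.random.SeedSequence(7)
    )
    return hidden, pop, trace


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def short_hidden():
    """A 5 s telegraph trace at the default time step."""
    return si.simulate_hidden_state(si.MarkovParams(20 / 3, 40 / 3, 2e-4, 5.0, seed=3))
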
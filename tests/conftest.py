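import numpy as np
import pytest

from equigait import simulate as sim


@pytest.fixture(scope="session")
def walk_clean():
    """Noise-free walk trial, systems already aligned (lag 0)."""
    g = sim.GaitConfig.walk(n_strides=12)
    s = sim.SensorConfig.noiseless(lag=0.0)
    return sim.simulate_trial(g, s)


@pytest.fixture(scope="session")
def walk_noisy():
    """Walk trial at realistic noise with injected sacrum asymmetry and a
    fractional-sample inter-system lag."""
    g = sim.GaitConfig.walk(n_strides=12, asymmetry={"sacrum": (10.0, 6.0)})
    s = sim.SensorConfig(seed=42)
    return sim.simulate_trial(g, s)


@pytest.fixture(scope="session")
def trot_clean():
    g = sim.GaitConfig.trot(n_strides=12)
    s = sim.SensorConfig.noiseless(lag=0.0)
    return sim.simulate_trial(g, s)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
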
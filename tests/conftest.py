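import numpy as np
import pytest

from driftswitch.model import BaselineModel, BasisConfig, ModelParams, NeuronParams
from driftswitch.simulate import random_neurons, simulate_session


def intercept_neuron(w_ea: float, w_dc: float, rate: float = 10.0) -> NeuronParams:
    """Neuron with an intercept-only baseline at the given firing rate."""
    coef = np.array([np.log(np.expm1(rate))])
    return NeuronParams(w_ea=w_ea, w_dc=w_dc, baseline=BaselineModel(coef, BasisConfig.intercept_only()))


@pytest.fixture(scope="session")
def demo_params() -> ModelParams:
    rng = np.random.default_rng(7)
    neurons = random_neurons(6, rng, weight_scale=2.0)
    return ModelParams(bound=3.5, sigma_s2=1.0, mu0=0.2, neurons=neurons, n_interior=51)


@pytest.fixture(scope="session")
def demo_session(demo_params):
    return simulate_session(demo_params, 40, seed=11).session


@pytest.fixture(scope="session")
def demo_sim(demo_params):
    return simulate_session(demo_params, 40, seed=11)
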
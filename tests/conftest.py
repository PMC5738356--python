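import numpy as np
import pytest

from spikeforce.neurons import NeuronParams
from spikeforce.synapses import SynapseParams, WeightConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_lif_net():
    """A small LIF network bundle for integration tests (seconds units)."""
    return dict(
        neuron=NeuronParams.lif(time_unit="s"),
        weights=WeightConfig(N=300, p=0.1, G=0.04, Q=10.0, seed=7),
        synapse=SynapseParams(tau_r=2e-3, tau_d=20e-3),
    )
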
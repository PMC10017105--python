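import numpy as np
import pytest

from cagc.recording import FluorescenceRecording, NeuronMeta
from cagc.simulate import benchmark_network, simulate_var


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def white_noise_recording(rng):
    """4 independent white-noise neurons, T=400."""
    return FluorescenceRecording(signal=rng.normal(size=(4, 400)), dt=0.25)


@pytest.fixture
def var_recording():
    """Benchmark VAR recording (10 neurons, T=2000, seeded)."""
    return simulate_var(benchmark_network(), 2000, seed=3).recording


@pytest.fixture
def two_chain_meta():
    """Metadata for a 10-neuron two-chain layout (5 left, 5 right)."""
    meta = []
    for side, x in (("L", -10.0), ("R", 10.0)):
        for k in range(5):
            meta.append(
                NeuronMeta(label=f"{side}{k}", side=side, rostrocaudal_rank=k, position=(x, -10.0 * k))
            )
    return tuple(meta)
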
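import numpy as np
import pytest

from calspike import SimulationConfig, forward_calcium, generate_spike_train


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_recording():
    """A 30 s high-SNR recording with paired ground truth."""
    cfg = SimulationConfig(seed=7, duration_s=30.0, noise_sd=0.03, amplitude_cv=0.1)
    spikes = generate_spike_train(cfg)
    fluor = forward_calcium(spikes, cfg)
    return cfg, spikes, fluor
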
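import numpy as np
import pytest

from srnn_anomaly import PipelineConfig, WaveformSpec, generate


@pytest.fixture(scope="session")
def tiny_benchmark():
    """Six training beats, ten test beats with one ectopic anomaly."""
    train, _ = generate(WaveformSpec(n_beats=6, seed=3))
    test, labels = generate(
        WaveformSpec(n_beats=10, anomaly_spec=((5, "ectopic"),), seed=4))
    return train, test, labels


@pytest.fixture(scope="session")
def reduced_benchmark():
    """Thirty training beats, 24 test beats with three ectopic anomalies."""
    train, _ = generate(WaveformSpec(n_beats=30, seed=0))
    test, labels = generate(
        WaveformSpec(n_beats=24,
                     anomaly_spec=((6, "ectopic"), (13, "ectopic"), (20, "ectopic")),
                     seed=1))
    return train, test, labels


@pytest.fixture(scope="session")
def small_net_config():
    """A 50-neuron network config for fast plumbing tests."""
    from srnn_anomaly import NetworkConfig

    return NetworkConfig(N_exc=40, N_inh=10, N_input=5, P_in=0.3)
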
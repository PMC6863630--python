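import numpy as np
import pytest

from optopallidum.model import CurrentStepProtocol, LightStimProtocol
from optopallidum.oepsc import DetectionConfig
from optopallidum.synth import NoiseModel, SynapseParams


@pytest.fixture(scope="session")
def light_protocol():
    return LightStimProtocol()


@pytest.fixture(scope="session")
def step_protocol():
    return CurrentStepProtocol()


@pytest.fixture(scope="session")
def detection_config():
    return DetectionConfig()


@pytest.fixture
def clean_synapse():
    """Noise-free, jitter-free synapse for deterministic ground truth."""
    return SynapseParams(amplitude=50.0, latency_mean=3.0, latency_jitter_sd=0.0)


@pytest.fixture
def recording_noise():
    return NoiseModel(gaussian_sd=2.0)


@pytest.fixture(scope="session")
def hyperpolarizing_amplitudes():
    return np.array([-20.0, -40.0, -50.0, -60.0, -80.0, -100.0])
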
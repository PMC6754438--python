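import numpy as np
import pytest

from ttmkit.cleaning import CleaningConfig
from ttmkit.simulate import ExperimentDesign, default_waveforms, simulate_recording


@pytest.fixture(scope="session")
def ccfg() -> CleaningConfig:
    return CleaningConfig()


@pytest.fixture(scope="session")
def noise_free_recording():
    """One clean 7 s paced recording (all four channels) plus its waveforms."""
    design = ExperimentDesign(noise_sd=0.0, crosstalk_gain=0.1)
    wps = default_waveforms()
    traces = simulate_recording(wps, design, np.random.default_rng(0))
    return wps, traces
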
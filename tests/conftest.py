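import numpy as np
import pytest

from lamicsd import synth
from lamicsd.datatypes import LaminarRecording, default_layer_map


@pytest.fixture(scope="session")
def lmap32():
    return default_layer_map(32)


@pytest.fixture(scope="session")
def params_pre():
    return synth.SynthParams()


@pytest.fixture(scope="session")
def params_post(params_pre):
    return synth.hyase_effect(params_pre)


@pytest.fixture(scope="session")
def clean_params():
    """Noise-free, background-free parameters for closed-form checks."""
    return synth.SynthParams(
        noise_sd=0.0, background_gain=0.0, background_lateral=0.0
    )


@pytest.fixture()
def small_recording():
    rng = np.random.default_rng(0)
    return LaminarRecording(
        lfp=rng.standard_normal((4, 32, 400)),
        fs=2000.0,
        dz=0.05,
        condition="pre",
        subject_id="sub-01",
        stim_freq=np.repeat([1000.0, 2000.0], 2),
        stim_onset=100,
    )
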
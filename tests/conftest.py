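import warnings

import numpy as np
import pytest

from oscillotap.simulate import EffectSpec, SimConfig, generate_session
from oscillotap.tfr import build_wavelet_bank


@pytest.fixture(scope="session")
def bank256():
    return build_wavelet_bank(256.0)


@pytest.fixture(scope="session")
def small_session():
    """One reduced synthetic session: 35 channels (through T8), 512 Hz, blinks."""
    cfg = SimConfig(
        n_participants=1,
        n_channels=35,
        fs_raw=512.0,
        trial_duration=5.0,
        n_trials_per_condition=2,
        rates=(70.0,),
        conditions=("Relaxing", "ToneOnly"),
        blink_rate=30.0,
        erd_spec=(EffectSpec("Relaxing", (16.0, 30.0), (0.0, 400.0), 2.0, ("FCz",)),),
        seed=3,
    )
    return cfg, generate_session(cfg, 0)


@pytest.fixture()
def quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
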
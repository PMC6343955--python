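import numpy as np
import pytest

from neopain import EpochSpec, canonical_waveforms, make_noxious_template

FS = 500.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def waves(fs):
    return canonical_waveforms(fs)


@pytest.fixture(scope="session")
def nox_template(fs):
    return make_noxious_template(fs)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def quiet_spec(fs):
    """Noise-free, jitter-free single-channel epoch spec."""
    return EpochSpec(
        fs=fs, channels=["Cz"], noise_rms=0.0, snr=3.0, latency_jitter_sd_s=0.0
    )


@pytest.fixture()
def cz_spec(fs):
    """Noisy Cz-only spec at SNR 3 (keeps epoch simulations light)."""
    return EpochSpec(fs=fs, channels=["Cz"], noise_rms=1.0, snr=3.0)
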
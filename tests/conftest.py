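import numpy as np
import pytest

from emgforce import Envelope, SignalMatrix, SyntheticConfig, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Short 4-muscle synthetic recording with force noise (shared,
    read-only)."""
    return make_dataset(SyntheticConfig(duration_s=4.0, seed=7, noise_sd=0.05))


@pytest.fixture(scope="session")
def noisefree_dataset():
    """Noise-free recording: the exact generative model, for recovery
    tests."""
    return make_dataset(
        SyntheticConfig(duration_s=4.0, seed=11, noise_sd=0.0, n_channels_per_muscle=4)
    )


@pytest.fixture
def two_envelopes(rng):
    e = rng.random((500, 2)) * 0.9 + 0.05
    return [Envelope(e[:, i], fs=100.0, muscle_id=f"m{i + 1}") for i in range(2)]


def signal(data, fs=2048.0, **kw):
    return SignalMatrix(np.asarray(data, dtype=float), fs=fs, **kw)
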
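import numpy as np
import pytest

from mifala.signals import SyntheticConfig, generate_synthetic_mi


@pytest.fixture(scope="session")
def small_trials():
    """80 synthetic 4-class trials (12 channels, 4 informative, snr 2)."""
    cfg = SyntheticConfig(
        n_trials_per_class=20,
        n_channels=12,
        n_informative_channels=4,
        snr=2.0,
        seed=11,
    )
    return generate_synthetic_mi(cfg)


@pytest.fixture(scope="session")
def small_labels(small_trials):
    return np.array([t.label for t in small_trials])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
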
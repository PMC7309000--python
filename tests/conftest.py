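import numpy as np
import pytest

from eegfsel import BandEffect, SynthSpec, generate_synthetic_trials


@pytest.fixture(scope="session")
def small_trials():
    """Binary trial set, 8 channels, 4 s at 128 Hz, alpha effect on class +1."""
    spec = SynthSpec(
        n_trials_per_class=5,
        n_channels=8,
        fs=128.0,
        duration=4.0,
        band_effects={1: (BandEffect(8.0, 14.0, (0, 1, 2, 3), 3.0),)},
        seed=42,
    )
    return generate_synthetic_trials(spec)


@pytest.fixture(scope="session")
def montage_trials():
    """Trial set on the 30-channel online layout (has all asymmetry pairs)."""
    spec = SynthSpec(
        n_trials_per_class=3, n_channels=30, fs=128.0, duration=2.0, seed=7
    )
    return generate_synthetic_trials(spec)


def make_planted(n_per_class=30, n_features=100, n_informative=5, shift=1.0, seed=0):
    """Two balanced Gaussian classes separated by a mean shift on the first
    ``n_informative`` columns only."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.standard_normal((n, n_features))
    y = np.r_[np.ones(n_per_class), -np.ones(n_per_class)].astype(int)
    X[:n_per_class, :n_informative] += shift
    return X, y


@pytest.fixture(scope="session")
def planted():
    return make_planted(seed=11)
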
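import numpy as np
import pytest

from ecgipoly import SimConfig, generate_paired_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale acquisition: short record, modest lead counts, linear+clean."""
    return SimConfig(
        n_torso_leads=12,
        n_endo_leads=8,
        duration=0.5,
        sampling_rate=200.0,
        noise_sd=0.0,
        nonlinearity_gain=0.0,
        subtract_reference=False,
        seed=101,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_paired_dataset(small_config)


def diagonally_dominant(rng, n, scale=1.0):
    """Random strictly diagonally dominant (hence invertible) matrix."""
    a = rng.normal(size=(n, n)) * scale
    off = np.sum(np.abs(a), axis=1) - np.abs(np.diag(a))
    a[np.diag_indices(n)] = np.sign(np.diag(a) + (np.diag(a) == 0)) * (off + scale)
    return a
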
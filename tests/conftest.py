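import warnings

import numpy as np
import pytest

from cfrlineage import (
    CFRParams,
    SimSettings,
    cluster_dataset,
    generate_dataset,
    simulate_sde,
)


@pytest.fixture(scope="session")
def quiet_dataset_sigma0():
    """Noise-free high-oscillation snapshot (alpha=1000)."""
    return generate_dataset(
        CFRParams(alpha=1000.0), settings=SimSettings(sigma=0.0), seed=11
    )


@pytest.fixture(scope="session")
def noisy_dataset():
    """Moderate-noise high-oscillation snapshot for pipeline tests."""
    return generate_dataset(
        CFRParams(alpha=1000.0), settings=SimSettings(sigma=0.01), seed=12
    )


@pytest.fixture(scope="session")
def clustering_sigma0(quiet_dataset_sigma0):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cluster_dataset(quiet_dataset_sigma0, k=10, seed=3)


@pytest.fixture(scope="session")
def sde_path_sigma0():
    """One noise-free Euler-Maruyama path at alpha=1000 (defaults otherwise)."""
    return simulate_sde(
        CFRParams(alpha=1000.0), settings=SimSettings(sigma=0.0, seed=1)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
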
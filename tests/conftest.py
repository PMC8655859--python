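import numpy as np
import pandas as pd
import pytest

from ewaskit import simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Default-conditions dataset, scaled down for fast unit tests."""
    return simulate_dataset(n_samples=80, n_cpgs=3000, seed=101)


@pytest.fixture(scope="session")
def spiked_dataset():
    """Full-size spiked dataset for power-style checks."""
    return simulate_dataset(
        n_samples=120, n_cpgs=10000, spike_fraction=0.3, delta=0.05, seed=11
    )


@pytest.fixture(scope="session")
def null_dataset():
    """No diagnosis effect, no latent factors."""
    return simulate_dataset(
        n_samples=120, n_cpgs=10000, k_latent=0, delta=0.0, spike_fraction=0.3,
        seed=21,
    )


@pytest.fixture()
def tiny_beta():
    rng = np.random.default_rng(0)
    vals = rng.uniform(0.05, 0.95, size=(20, 6))
    from ewaskit import BetaMatrix

    return BetaMatrix(
        pd.DataFrame(
            vals,
            index=[f"cg{i:03d}" for i in range(20)],
            columns=[f"S{j}" for j in range(6)],
        )
    )
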
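import numpy as np
import pandas as pd
import pytest

from betanest import (
    SyntheticConfig,
    generate_species_pool,
    simulate_experiment,
    to_incidence,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_incidence(rng, n_samples=10, n_species=50, p=0.4) -> pd.DataFrame:
    mat = rng.uniform(size=(n_samples, n_species)) < p
    # guard against all-empty rows, which are a separate error path
    for i in range(n_samples):
        if not mat[i].any():
            mat[i, rng.integers(n_species)] = True
    return pd.DataFrame(
        mat,
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"sp{j}" for j in range(n_species)],
    )


@pytest.fixture(scope="session")
def small_experiment():
    """One mixed-regime simulated experiment at desk scale."""
    config = SyntheticConfig(seed=7, pool_size=120, depth_mean=3000)
    pool = generate_species_pool(config)
    counts, meta, env = simulate_experiment(pool, config)
    return config, pool, counts, meta, env


@pytest.fixture(scope="session")
def small_incidence(small_experiment):
    _, _, counts, _, _ = small_experiment
    inc = to_incidence(counts)
    return inc.loc[:, inc.any(axis=0)]
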
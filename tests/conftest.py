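import numpy as np
import pandas as pd
import pytest

from lfqimpute.core_data import IntensityTable
from lfqimpute.selection import simulate_missing_split
from lfqimpute.synthetic import apply_missingness, generate_complete


@pytest.fixture
def tiny_table():
    """2 samples x 2 features with one missing cell."""
    return IntensityTable(pd.DataFrame(
        [[24.0, 25.0], [30.0, np.nan]], index=["s1", "s2"], columns=["f1", "f2"]
    ))


@pytest.fixture(scope="session")
def small_observed():
    """40 x 60 rank-3 table with realistic missingness; session-cached."""
    truth = generate_complete(40, 60, rank=3, noise_sd=0.3, seed=11)
    return apply_missingness(truth, seed=12), truth


@pytest.fixture(scope="session")
def small_split(small_observed):
    table, _ = small_observed
    return simulate_missing_split(table, seed=13)


def random_table(rng, n_samples, n_features, missing=0.2):
    values = rng.normal(25, 3, size=(n_samples, n_features))
    mask = rng.random(values.shape) < missing
    values[mask] = np.nan
    return IntensityTable(pd.DataFrame(
        values,
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"f{j}" for j in range(n_features)],
    ))
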
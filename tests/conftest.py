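import numpy as np
import pandas as pd
import pytest

import blockcount as bc


def make_table(y, n_tests, x1=None, x2=None, x3=None):
    """Small literal block table with defaulted covariates."""
    y = np.asarray(y)
    n = len(y)
    rng = np.random.default_rng(20240501)
    return pd.DataFrame(
        {
            "block_id": [f"T{i:03d}" for i in range(n)],
            "y": y.astype(int),
            "n_tests": np.asarray(n_tests, dtype=int),
            "x1": np.asarray(x1) if x1 is not None else rng.normal(1923, 17, n),
            "x2": np.asarray(x2) if x2 is not None else rng.normal(4.0, 0.4, n),
            "x3": np.asarray(x3) if x3 is not None else rng.normal(5.2, 0.6, n),
        }
    )


@pytest.fixture(scope="session")
def fixture_dataset():
    return bc.make_paper_like_dataset(seed=1)


@pytest.fixture(scope="session")
def fixture_table(fixture_dataset):
    return fixture_dataset[0]


@pytest.fixture(scope="session")
def fixture_weights(fixture_dataset):
    return fixture_dataset[1]


@pytest.fixture(scope="session")
def small_table(fixture_table):
    """First 250 blocks of the fixture, for cheaper likelihood evaluations."""
    return fixture_table.iloc[:250].reset_index(drop=True)
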
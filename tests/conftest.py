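import numpy as np
import pandas as pd
import pytest

from nbshrink import CountDataset, estimate_size_factors, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_sim():
    """A small two-group simulated dataset shared by read-only tests."""
    return simulate_dataset(n_genes=300, m=6, de_fraction=0.2, seed=3)


@pytest.fixture
def two_group_info():
    def make(m: int) -> pd.DataFrame:
        half = m // 2
        return pd.DataFrame(
            {"condition": ["A"] * half + ["B"] * (m - half)},
            index=[f"s{j}" for j in range(m)],
        )

    return make


def make_dataset(counts, sample_info=None, size_factors=None) -> CountDataset:
    ds = CountDataset(np.asarray(counts), sample_info)
    if size_factors is not None:
        ds.set_size_factors(np.asarray(size_factors, dtype=float))
    else:
        try:
            estimate_size_factors(ds)
        except ValueError:
            pass
    return ds
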
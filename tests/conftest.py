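import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from crossomics import CountTable, SimConfig, generate_universe

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture
def small_counts():
    """Three proteins, two samples, hand-checkable."""
    counts = pd.DataFrame(
        {"s1": [10, 20, 30], "s2": [10, 10, 0]},
        index=pd.Index(["p1", "p2", "p3"], name="feature_id"),
    )
    lengths = pd.Series([100, 200, 300], index=counts.index, dtype=float)
    return CountTable(counts, lengths)


@pytest.fixture(scope="session")
def default_universe():
    return generate_universe(SimConfig(seed=11))
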
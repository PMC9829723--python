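import numpy as np
import pandas as pd
import pytest

from soilhealth import OtuTable, RatingsTable, RATING_NAMES, SimConfig, simulate_survey


@pytest.fixture
def tiny_counts() -> pd.DataFrame:
    return pd.DataFrame(
        [[1, 2, 3], [4, 5, 6]],
        index=["s1", "s2"],
        columns=["o1", "o2", "o3"],
    )


@pytest.fixture
def tiny_table(tiny_counts) -> OtuTable:
    return OtuTable(tiny_counts.copy())


@pytest.fixture
def flat_ratings() -> RatingsTable:
    """Four samples, all twelve ratings set to 50."""
    idx = [f"s{i}" for i in range(4)]
    return RatingsTable(pd.DataFrame(50.0, index=idx, columns=list(RATING_NAMES)))


@pytest.fixture(scope="session")
def small_survey():
    """One modest survey reused across read-only tests."""
    return simulate_survey(SimConfig(n_samples=80, n_otus=150, seed=11))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
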
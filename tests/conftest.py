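import numpy as np
import pandas as pd
import pytest

from ntracer.fixtures import table2_long
from ntracer.simulate import CommunityScenario, simulate_community


@pytest.fixture(scope="session")
def rates_long() -> pd.DataFrame:
    """Tidy volumetric rates from the packaged study table."""
    return table2_long()


@pytest.fixture(scope="session")
def community_fixture():
    """A moderate simulated community table with fraction labels and truth."""
    return simulate_community(CommunityScenario(n_samples=20, seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
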
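import numpy as np
import pandas as pd
import pytest

from rootpatch import SimConfig
from rootpatch.synthetic_data import generate_dataset


@pytest.fixture(scope="session")
def small_cfg():
    """A desk-scale study: 6 sites in 3 regions, full 30-plot transects."""
    return SimConfig(sites_per_region=(2, 2, 2), n_species=60,
                     species_per_site=20, seed=11)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return generate_dataset(small_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def two_species_traits():
    return pd.DataFrame({"sla": [10.0, 30.0]}, index=["sp1", "sp2"])
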
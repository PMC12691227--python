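import warnings

import numpy as np
import pytest

from wsiprog.synthetic import SyntheticCohortConfig, generate_cohort

warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def small_cohort():
    """20 patients with rendered 64x64 grids and 16-px tiles."""
    cfg = SyntheticCohortConfig(n_patients=20, tile_size=16, rng_seed=3)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def grid0(small_cohort):
    return small_cohort.grids[0]


@pytest.fixture(scope="session")
def provider0(small_cohort):
    return small_cohort.tile_provider(0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
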
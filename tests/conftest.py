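import numpy as np
import pytest

import octshap as o


@pytest.fixture(scope="session")
def zone_map():
    return o.default_zone_map()


@pytest.fixture(scope="session")
def small_config():
    """A small cohort: quick to generate, both classes well represented."""
    return o.CohortConfig(n_patients=12, n_controls=10, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return o.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_table(small_cohort, zone_map):
    return o.build_feature_table(small_cohort, zone_map)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
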
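import numpy as np
import pytest

from daplex.cohort_synth import default_lrti_config, generate_cohort
from daplex.pool import COMPACT_GRIDS, COMPACT_META_GRID


@pytest.fixture(scope="session")
def lrti_config():
    return default_lrti_config()


@pytest.fixture(scope="session")
def cohort(lrti_config):
    """One default synthetic cohort, shared across tests."""
    return generate_cohort(lrti_config, seed=11)


@pytest.fixture(scope="session")
def feature_columns(lrti_config):
    return [v.name for v in lrti_config.variables]


@pytest.fixture(scope="session")
def column_types(lrti_config):
    cont = [v.name for v in lrti_config.variables if v.var_type == "continuous"]
    cat = [v.name for v in lrti_config.variables if v.var_type != "continuous"]
    return cont, cat


@pytest.fixture(scope="session")
def compact_grids():
    """Single-configuration grids for fast end-to-end tests."""
    return dict(COMPACT_GRIDS), dict(COMPACT_META_GRID)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
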
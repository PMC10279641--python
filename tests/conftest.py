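import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from qpipe.allometry import default_registry
from qpipe.geometry import TreeRecord
from qpipe.synthetic import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture()
def sample_tree():
    return TreeRecord("t1", species="Abies", pft="EC", a_bh=0.04,
                      height=15.0, crown_base_height=8.0)


@pytest.fixture(scope="session")
def default_dataset():
    """One medium synthetic inventory reused by read-only tests."""
    cfg = SimulationConfig(n_trees=400, n_species=20, seed=7)
    records, truth = generate_dataset(cfg)
    return cfg, records, truth


def random_loglog(rng, n=40, slope=1.1, intercept=0.5, sd=0.3, x_sd=1.0):
    """Helper: one random log-log dataset with known line."""
    x = rng.normal(0.0, x_sd, n)
    y = intercept + slope * x + rng.normal(0.0, sd, n)
    return x, y
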
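"""Shared fixtures: all data are generated programmatically at test time."""

import numpy as np
import pandas as pd
import pytest

from methylsubtypes.simulate import SimulationConfig, generate_methylation_cohorts


@pytest.fixture(scope="session")
def tiny_config():
    """Small but signal-bearing multi-cohort configuration for unit tests."""
    return SimulationConfig(
        n_load_per_cohort=90,
        n_hc_per_cohort=45,
        n_probes=2500,
        n_genes=400,
        n_sc_genes=200,
        n_sc_samples=24,
        cells_per_state=8,
        n_states=4,
        n_included_states=3,
        sc_degs_per_state=6,
        n_regions_per_scenario=2,
        panel_size=200,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohorts(tiny_config):
    return generate_methylation_cohorts(tiny_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_cloud_data(rng):
    """Two well-separated Gaussian clouds (20 features)."""
    a = rng.normal(0.0, 0.3, size=(20, 20))
    b = rng.normal(4.0, 0.3, size=(15, 20))
    x = np.vstack([a, b])
    labels = np.array([1] * 20 + [2] * 15)
    return pd.DataFrame(x), labels
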
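import numpy as np
import pandas as pd
import pytest

from hbcgm.synthetic_data import (
    CohortSimConfig,
    PanelSimConfig,
    default_latency_block,
    simulate_cohort,
    simulate_strain_panel,
)


@pytest.fixture(scope="session")
def latency_panel():
    """One 17-strain panel with the default 3-group causal latency block."""
    config = PanelSimConfig(seed=42, causal_block=default_latency_block())
    matrix, phenotype, annotation, truth = simulate_strain_panel(config)
    return matrix, phenotype, annotation, truth


@pytest.fixture(scope="session")
def clean_panel():
    """Small panel with no missing calls (exact block structure)."""
    config = PanelSimConfig(
        seed=7, n_sites=600, missing_rate=0.0,
        causal_block=default_latency_block(),
    )
    return simulate_strain_panel(config)


@pytest.fixture(scope="session")
def null_cohort():
    """85-patient cohort with no causal SNP effect."""
    cohort, truth = simulate_cohort(CohortSimConfig(seed=11))
    return cohort, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
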
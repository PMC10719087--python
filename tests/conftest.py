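import numpy as np
import pytest

from epiretro.simulate import SimulationConfig, simulate_multiomic_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest seeded cohort shared across read-only tests."""
    cfg = SimulationConfig(
        n_clusters=4,
        cells_per_cluster_mc=50,
        cells_per_cluster_rna=50,
        n_genes=200,
        marker_fraction=0.3,
        marker_effect=0.3,
        coverage_mean=80.0,
        n_projections=2,
        seed=11,
    )
    return cfg, simulate_multiomic_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
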
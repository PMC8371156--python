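import numpy as np
import pytest

from morphoscore import CohortConfig, SceneSpec, render_field, simulate_feature_table


@pytest.fixture(scope="session")
def strong_cohort():
    """Small cohort with a strong planted genotype shift."""
    cfg = CohortConfig(n_group0=5, n_group1=5, cells_per_individual=120,
                       effect_size=1.5, affected_count=40, individual_sd=0.3,
                       seed=11)
    return cfg, simulate_feature_table(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no group effect at all."""
    cfg = CohortConfig(n_group0=5, n_group1=5, cells_per_individual=120,
                       effect_size=0.0, affected_count=0, individual_sd=0.3,
                       seed=12)
    return cfg, simulate_feature_table(cfg)


@pytest.fixture(scope="session")
def rendered_field():
    """A small rendered five-channel field with ground truth."""
    spec = SceneSpec(n_cells=6, image_size=360, seed=5)
    return spec, render_field(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
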
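import numpy as np
import pytest

from agemod.synthdata import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small complete-trait cohort with mild signal, reused across tests."""
    cfg = CohortConfig(
        n_subjects=300,
        n_nuisance_confounds=12,
        idp_category_sizes={"volume": 6, "area": 4, "thickness": 4},
        trait_count=5,
        base_slope=0.3,
        idp_missing_rate=0.02,
        seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
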
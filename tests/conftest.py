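import numpy as np
import pytest

from dynstates import cohort as coh
from dynstates import validation as val


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-group cohort with no injected effects (null design)."""
    cfg = coh.CohortConfig(n_group_a=6, n_group_b=6, C=14, T=160, seed=5)
    return coh.generate_cohort(cfg)


@pytest.fixture(scope="session")
def recovery_study():
    """20 replicate cohorts with separated templates and injected effects.

    Shared across the state-recovery and effect-recovery acceptance tests
    because both are scored on the same study conditions.
    """
    return val.run_recovery_study(n_cohorts=20, seed=101)


@pytest.fixture(scope="session")
def classifier_report():
    """Separable-feature LOOCV plus 20 permuted-label leakage runs."""
    return val.classifier_sanity(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
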
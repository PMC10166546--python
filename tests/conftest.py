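import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vfarch import (
    ArchetypalAnalysis,
    decompose_records,
    recovery_benchmark_spec,
    simulate_cohort,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def recovery_cohort():
    """240-field longitudinal cohort mixed from the 5 identifiable planted
    patterns (Dirichlet 0.3, 1 dB noise) with known truth."""
    return simulate_cohort(recovery_benchmark_spec(n_patients=40, seed=1))


@pytest.fixture(scope="session")
def recovery_fit(recovery_cohort):
    """Best-of-restarts k=5 archetype fit of the recovery cohort."""
    records, _ = recovery_cohort
    X = np.stack([r.td for r in records])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        est = ArchetypalAnalysis(
            n_archetypes=5, n_restarts=2, max_iter=50, random_state=1
        ).fit(X)
    return est


@pytest.fixture(scope="session")
def recovery_decs(recovery_cohort, recovery_fit):
    records, _ = recovery_cohort
    return decompose_records(records, recovery_fit)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
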
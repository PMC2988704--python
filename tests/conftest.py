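import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ctclassify as ctc

settings.register_profile(
    "suite",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cohort():
    """One default-noise simulated cohort shared across tests."""
    return ctc.simulate_cohort(ctc.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """A zero-noise cohort where every relation is exact."""
    cfg = ctc.SimulationConfig(
        seed=5,
        n_samples=20,
        platform_a_noise_sd=0.0,
        ct_noise_sd=0.0,
        replicate_noise_sd=0.0,
    )
    return ctc.simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


def cohort_delta_ct(cohort):
    agg = ctc.aggregate_replicates(cohort.ct_wells)
    return ctc.delta_ct(agg, cohort.config.reference_gene)
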
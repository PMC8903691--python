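import numpy as np
import pytest

from megconn.pipeline import PipelineConfig
from megconn.synthetic import CohortSpec, default_network_specs, generate_cohort


@pytest.fixture(scope="session")
def default_nets():
    return default_network_specs("gamma", 1000.0)


@pytest.fixture(scope="session")
def small_cohort_spec():
    return CohortSpec(
        n_patients=3,
        n_controls=3,
        n_trials=20,
        trial_len_s=0.24,
        n_channels=32,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(default_nets, small_cohort_spec):
    net_p, net_c = default_nets
    return generate_cohort(small_cohort_spec, net_p, net_c)


@pytest.fixture(scope="session")
def smoke_config(small_cohort_spec):
    return PipelineConfig(cohort=small_cohort_spec, gc_max_lag_ms=6.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
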
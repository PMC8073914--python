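import numpy as np
import pandas as pd
import pytest

from driverscope.synthetic_cohort import (
    CohortParams,
    generate_cohort,
    generate_regulators,
)


@pytest.fixture(scope="session")
def small_cohort():
    """150-sample, 400-gene cohort with 12 planted drivers (6 prognostic)."""
    params = CohortParams(n_samples=150, n_genes=400, n_drivers=12)
    bundle, truth, control = generate_cohort(params, seed=11)
    return bundle, truth, control


@pytest.fixture(scope="session")
def small_cohort_with_regulators(small_cohort):
    bundle, truth, control = small_cohort
    mirna, tf, interactions, truth = generate_regulators(bundle, truth, seed=11)
    bundle.expression["mirna"] = mirna
    bundle.expression["tf"] = tf
    return bundle, truth, control, interactions


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def exponential_survival(rng, n, hazard, censor_horizon):
    """Exponential event times with uniform administrative censoring."""
    t_event = rng.exponential(1.0 / hazard, size=n)
    t_cens = rng.uniform(0, censor_horizon, size=n)
    return np.minimum(t_event, t_cens), (t_event <= t_cens).astype(float)
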
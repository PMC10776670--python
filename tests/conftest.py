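import logging

import numpy as np
import pytest

import exprsurv as es

# subgroup-scan and scan warnings about skipped strata are expected in tests
logging.getLogger("exprsurv").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def small_cohort():
    """400-patient cohort with a two-fold hazard step at expression 0.33."""
    return es.generate_cohort(es.CohortSpec(n_patients=400, seed=7))


@pytest.fixture(scope="session")
def null_cohort():
    return es.generate_null_cohort(es.CohortSpec(n_patients=300, seed=11))


def random_survival_dataset(rng, n=None, binary=False, with_ties=False):
    """Small random survival dataset for oracle comparisons."""
    n = n or int(rng.integers(20, 50))
    if binary:
        x = (rng.random(n) < 0.5).astype(float)
        if x.sum() in (0, n):
            x[0] = 1 - x[0]
    else:
        x = rng.normal(size=n)
    t = rng.exponential(scale=np.exp(-0.4 * x))
    if with_ties:
        t = np.ceil(t * 4) + 1.0
    e = rng.random(n) < 0.75
    if e.sum() < 2:
        e[:2] = True
    return t, e, x
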
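import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import ineqop as iq
from ineqop.selection import LassoConfig


@pytest.fixture(scope="session")
def default_params():
    return iq.default_params()


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-structure cohort: long table + role map."""
    params = iq.default_params(n_individuals=600, seed=11)
    long, rolemap = iq.simulate_cohort(params)
    return params, long, rolemap


@pytest.fixture(scope="session")
def small_frame(small_cohort):
    params, long, rolemap = small_cohort
    return iq.prepare(long, rolemap, iq.FilterCriteria(age_range=(25, 65)))


@pytest.fixture(scope="session")
def fast_lasso():
    """Lighter CV settings for tests that loop over many fits."""
    return LassoConfig(k_folds=5, n_lambda=30)


def make_params(n=2000, seed=0, **overrides):
    return replace(iq.default_params(n_individuals=n, seed=seed), **overrides)


@pytest.fixture(scope="session")
def clean_params():
    """Default structure without wave noise, missingness, or the income
    exp-transform: observed data match the latent structural model."""
    return make_params(n=20000, seed=3, n_waves=1, wave_noise_sd=0.0,
                      missing_rate=0.0, exp_outcomes=())


@pytest.fixture(scope="session")
def clean_frame(clean_params):
    long, rolemap = iq.simulate_cohort(clean_params)
    return iq.prepare(long, rolemap)
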
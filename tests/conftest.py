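import numpy as np
import pytest

import streamtemp as st


@pytest.fixture(scope="session")
def year_windows():
    """Windows over the full calendar year 2001 (two full half-years)."""
    return st.build_windows(np.arange(np.datetime64("2001-01-01"),
                                      np.datetime64("2002-01-01")))


@pytest.fixture(scope="session")
def small_scenario():
    return st.SimulationScenario(
        years=2, seed=42,
        wt_missing=st.MissingSpec(0.10, 12.0),
        at_missing=st.MissingSpec(0.01, 3.0),
        q_missing=st.MissingSpec(0.01, 3.0),
    )


@pytest.fixture(scope="session")
def small_data(small_scenario):
    """Two years of synthetic daily data with modest gaps, plus its truth."""
    return st.simulate_dataset(small_scenario)


@pytest.fixture(scope="session")
def small_fit(small_data):
    """A light but usable M2 fit of the two-year dataset (shared, read-only)."""
    data, truth = small_data
    mcmc = st.McmcConfig(n_chains=2, n_burnin=600, n_keep=600, seed=7)
    draws, report = st.fit(data, mcmc=mcmc)
    return draws, report, truth


@pytest.fixture(scope="session")
def nodis_fit():
    """A small fit of the air-temperature-only (no discharge) configuration."""
    data, truth = st.simulate_dataset(
        st.SimulationScenario(years=2, seed=5, use_discharge=False,
                              wt_missing=st.MissingSpec(0.05, 8.0)))
    mcmc = st.McmcConfig(n_chains=2, n_burnin=400, n_keep=400, seed=3,
                         use_discharge=False)
    draws, report = st.fit(data, mcmc=mcmc, check_convergence=False)
    return draws, truth
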
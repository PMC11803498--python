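import numpy as np
import pytest

from bcmeta import (
    HyperPriorConfig,
    McmcConfig,
    ScenarioConfig,
    covid_fixture,
    fit_bc_bnp,
    simulate_scenario,
)


@pytest.fixture(scope="session")
def covid():
    return covid_fixture()


@pytest.fixture(scope="session")
def fast_mcmc():
    """Short chain layout shared by the smoke-level model fits."""
    return McmcConfig(chains=4, iterations=4_000, burn_in=1_000, seed=1234)


@pytest.fixture(scope="session")
def biased_sim():
    """One N=20, 50%-planted-bias synthetic meta-analysis."""
    return simulate_scenario(ScenarioConfig.from_grid(20, 50, seed=7))


@pytest.fixture(scope="session")
def bnp_fit(biased_sim, fast_mcmc):
    """A BC-BNP fit on the planted-bias data, reused across postprocess tests."""
    return fit_bc_bnp(biased_sim.data, HyperPriorConfig(), fast_mcmc)


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    import warnings

    from bcmeta import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_926)
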
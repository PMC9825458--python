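import numpy as np
import pytest

from curvepool import MCMCConfig, SimScenario, fit_curve, simulate_experiment

#: reduced sampler settings for tests that need many fits; the default
#: (3 x 5000, 500 burn-in) settings are exercised where the contract is about
#: those settings themselves.
FAST_MCMC = dict(n_chains=3, n_iterations=1500, n_burn_in=300)


@pytest.fixture(scope="session")
def fitted_pair():
    """One full-settings fit on a well-behaved two-dataset experiment."""
    data = simulate_experiment(SimScenario(true_a=-1.0, true_k=1.5, seed=3))
    chains, summary = fit_curve(data, config=MCMCConfig(master_seed=7))
    return data, chains, summary


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
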
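import numpy as np
import pytest

from mggum import (
    McmcConfig,
    SimulationCondition,
    build_model,
    fit,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small 2-trait dataset with covariates and missingness."""
    cond = SimulationCondition(
        n_persons=120, n_traits=2, items_per_trait=4, n_options=2,
        missing_prop=0.10, trait_cor=0.5, trait_covariate_cor=0.25,
    )
    return simulate_dataset(cond, np.random.default_rng(2024))


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """One full-length fit (paper MCMC settings) reused across tests."""
    model = build_model(small_sim.responses, small_sim.items, small_sim.scale,
                        X=small_sim.persons.X)
    return fit(model, McmcConfig(seed=11))
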
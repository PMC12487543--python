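import numpy as np
import pytest

import motomort as mm


@pytest.fixture(scope="session")
def small_config():
    """3 countries x 5 cities, default rates; cheap enough to share."""
    return mm.SimulationConfig(n_countries=3, cities_per_country=5, seed=1)


@pytest.fixture(scope="session")
def small_study_inputs(small_config):
    return mm.generate_study(small_config)


@pytest.fixture(scope="session")
def small_study(small_config, small_study_inputs):
    exposures, deaths, population, factors, _ = small_study_inputs
    return mm.prepare_study(deaths, population, factors, exposures,
                            n_draws=5, seed=small_config.seed)


@pytest.fixture(scope="session")
def nb_fixture():
    """Small NB2 mixed dataset simulated directly from the model."""
    rng = np.random.default_rng(12345)
    n_groups, per = 12, 20
    n = n_groups * per
    X = np.column_stack([np.ones(n), rng.normal(size=n),
                         rng.binomial(1, 0.4, size=n)])
    offset = np.log(rng.uniform(1e3, 5e4, size=n))
    groups = np.repeat(np.arange(n_groups), per)
    beta = np.array([-7.5, -0.15, 0.3])
    b = 0.35 * rng.standard_normal(n_groups)
    mu = np.exp(X @ beta + offset + b[groups])
    alpha = 0.4
    y = rng.poisson(rng.gamma(1.0 / alpha, alpha * mu))
    return {"y": y.astype(float), "X": X, "offset": offset, "groups": groups,
            "beta": beta, "alpha": alpha, "sigma": 0.35}
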
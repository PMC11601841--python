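import numpy as np
import pytest
from hypothesis import settings

import smallarea as sa

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

FIXTURE_SEED = 7
FIXTURE_YEAR = 2019


@pytest.fixture(scope="session")
def lattice10():
    return sa.make_lattice(10, 10)


@pytest.fixture(scope="session")
def sim_config():
    return sa.SimulationConfig()


@pytest.fixture(scope="session")
def fixture_data(lattice10, sim_config):
    """Default synthetic registry: 10x10 lattice, 4 ages, 2 sexes, 2 races,
    5 years, spatial SD 0.3."""
    table, truth, pops = sa.simulate_registry(lattice10, sim_config, FIXTURE_SEED)
    return table, truth, pops


@pytest.fixture(scope="session")
def fixture_fit(lattice10, sim_config, fixture_data):
    """Full MCMC run on the default fixture (the long test of the suite)."""
    table, truth, pops = fixture_data
    df = table.query("colorectal", "incidence")
    spec = sa.ModelSpec(
        age_groups=sim_config.age_groups, years=sim_config.years, seed=FIXTURE_SEED
    )
    draws = sa.fit(df, lattice10, spec)
    return draws, df


@pytest.fixture(scope="session")
def fixture_rows(lattice10, fixture_fit):
    draws, df = fixture_fit
    query = sa.validate_query("colorectal", outcome="incidence")
    return sa.build_estimates(
        draws, sa.FLAT_4, lattice10, df, query, year=FIXTURE_YEAR
    )


@pytest.fixture
def tiny_draws():
    """Hand-constructible posterior container for unit tests of the
    estimate operations (1 chain; values set by each test)."""

    def build(mu, alpha, u, v, gamma=None, years=(2019,), age_groups=None):
        mu = np.atleast_1d(np.asarray(mu, dtype=float))
        alpha = np.asarray(alpha, dtype=float)
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        D = mu.shape[0]
        if alpha.ndim == 1:
            alpha = np.tile(alpha, (D, 1))
        if u.ndim == 1:
            u = np.tile(u, (D, 1))
        if v.ndim == 1:
            v = np.tile(v, (D, 1))
        T = len(years)
        if gamma is None:
            gamma = np.zeros((D, T))
        else:
            gamma = np.asarray(gamma, dtype=float)
            if gamma.ndim == 1:
                gamma = np.tile(gamma, (D, 1))
        if age_groups is None:
            age_groups = tuple(f"a{i}" for i in range(alpha.shape[1]))
        spec = sa.ModelSpec(
            age_groups=tuple(age_groups),
            years=tuple(years),
            iterations=2,
            burn_in=1,
            thin=1,
        )
        I = u.shape[1]
        ones = np.ones((1, D))
        return sa.PosteriorDraws(
            mu=mu[None, :],
            alpha=alpha[None],
            u=u[None],
            v=v[None],
            gamma=gamma[None],
            tau_u=ones.copy(),
            tau_v=ones.copy(),
            tau_g=ones.copy(),
            spec=spec,
            seed=0,
            area_ids=[f"A{i}" for i in range(I)],
        )

    return build
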
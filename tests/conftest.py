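import numpy as np
import pytest

import promstruct as ps


@pytest.fixture(scope="session")
def ikdc():
    return ps.builtin_ikdc()


@pytest.fixture(scope="session")
def population():
    return ps.default_population()


@pytest.fixture(scope="session")
def cohort600(population):
    """A moderate simulated cohort shared by read-only tests."""
    return ps.simulate(ps.SimulationConfig(n_respondents=600, seed=20, population=population))


@pytest.fixture(scope="session")
def moments600(cohort600):
    return ps.sample_moments(cohort600)


@pytest.fixture(scope="session")
def bifactor_6item():
    """Small worked bifactor model: 6 items, lambda_g=0.6, lambda_s=0.4,
    theta=0.48, two specific groups of three."""
    spec = ps.FactorModelSpec(
        name="bi6",
        factors=(("g", ("a", "b", "c", "d", "e", "f")), ("s1", ("a", "b", "c")), ("s2", ("d", "e", "f"))),
        covariance="orthogonal",
        general_factor="g",
    )
    lam = np.zeros((6, 3))
    lam[:, 0] = 0.6
    lam[:3, 1] = 0.4
    lam[3:, 2] = 0.4
    theta = np.full(6, 0.48)
    model = ps.FittedModel(
        spec=spec,
        item_ids=list("abcdef"),
        loadings=lam,
        phi=np.eye(3),
        theta=np.diag(theta),
        discrepancy=0.0,
        df=ps.model_df(spec),
        n_free_parameters=spec.n_free_parameters(),
        n_obs=500,
    )
    return model
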
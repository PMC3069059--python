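import numpy as np
import pytest

from pstrim import ScenarioSpec, default_scenario, simulate_dataset

ROLES_1BASED = {0: "confounder", 1: "confounder", 2: "confounder",
                3: "confounder", 4: "exposure_only", 5: "exposure_only",
                6: "exposure_only", 7: "outcome_only", 8: "outcome_only",
                9: "outcome_only"}


def make_spec(**overrides) -> ScenarioSpec:
    """A minimal valid scenario-1-shaped spec for toy constructions."""
    fields = dict(
        scenario_id=1,
        covariate_roles=ROLES_1BASED,
        exposure_intercept=0.0,
        exposure_main_coefs=(0.8, -0.25, 0.6, -0.4, -0.8, -0.5, 0.7,
                             0.0, 0.0, 0.0),
        outcome_intercept=0.0,
        outcome_coefs=(0.3, -0.36, -0.73, -0.2, 0.0, 0.0, 0.0,
                       0.71, -0.19, 0.26),
        outcome_basis="observed",
        outcome_noise_sd=0.0,
    )
    fields.update(overrides)
    return ScenarioSpec(**fields)


@pytest.fixture(scope="session")
def scenario1():
    return default_scenario(1)


@pytest.fixture(scope="session")
def scenario2():
    return default_scenario(2)


@pytest.fixture(scope="session")
def scenario3():
    return default_scenario(3)


@pytest.fixture(scope="session")
def dataset1(scenario1):
    """One scenario-1 replicate at the study's sample size."""
    return simulate_dataset(scenario1, 500, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
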
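import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import breathecon as bc

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def design():
    return bc.default_design()


@pytest.fixture(scope="session")
def truth():
    return bc.default_truth()


@pytest.fixture(scope="session")
def identifiable_truth(design, truth):
    """Ground-truth coefficients re-expressed in the dummy parameterisation."""
    return bc.reexpress(truth.true_coefficients, design)


@pytest.fixture(scope="session")
def sim_dataset(design, truth):
    """Moderate simulated choice dataset shared across read-only tests."""
    return bc.simulate_choice_data(design, truth, n_respondents=120, n_tasks=6, seed=42)


@pytest.fixture(scope="session")
def fitted(sim_dataset):
    return bc.fit_conditional_logit(sim_dataset)


@pytest.fixture(scope="session")
def life_table():
    return bc.synth_life_table()


@pytest.fixture(scope="session")
def cohort():
    return bc.CohortSpec(age_start=75, sex="male", diagnosis="COPD", uptake=0.85)


@pytest.fixture(scope="session")
def trial(truth):
    return bc.synth_trial_payoffs(truth, n_patients_per_arm=100, seed=3)


@pytest.fixture
def tiny_design():
    return [bc.Attribute("a", ("x", "y"), reference_level="x")]


@pytest.fixture(scope="session")
def flat_mortality():
    """Constant annual mortality so per-cycle death probability is exactly 0.1."""
    import pandas as pd

    p = 1.0 - 0.9**4
    rows = [
        {"age": a, "sex": s, "annual_all_cause": p, "annual_respiratory": p}
        for a in range(60, 101)
        for s in ("male", "female")
    ]
    return bc.MortalitySchedule(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def zero_mortality():
    import pandas as pd

    rows = [
        {"age": a, "sex": s, "annual_all_cause": 0.0, "annual_respiratory": 0.0}
        for a in range(60, 101)
        for s in ("male", "female")
    ]
    return bc.MortalitySchedule(pd.DataFrame(rows))
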
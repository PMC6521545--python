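import pytest

from cupfa import CupPlan, default_reference, default_study_table
from cupfa.surrogate import DEFAULT_GRID, fit_surrogate, generate_grid


@pytest.fixture(scope="session")
def studies():
    return default_study_table()


@pytest.fixture(scope="session")
def reference():
    return default_reference()


@pytest.fixture(scope="session")
def plan_40_20():
    return CupPlan(40.0, 20.0)


@pytest.fixture(scope="session")
def default_grid_samples():
    return generate_grid(DEFAULT_GRID)


@pytest.fixture(scope="session")
def fitted_surrogate(default_grid_samples):
    return fit_surrogate(default_grid_samples)
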
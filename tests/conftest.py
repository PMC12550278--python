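import numpy as np
import pytest

from midvif import task
from midvif.bias import build_subject_designs
from midvif.design import build_cuefeedback_design, build_saturated_design


@pytest.fixture(scope="session")
def params():
    return task.BehaviorModelParams()


@pytest.fixture(scope="session")
def run(params):
    return task.simulate_run(params, run_id=0, seed=123)


@pytest.fixture(scope="session")
def sat_design(run):
    return build_saturated_design(run)


@pytest.fixture(scope="session")
def cf_design(run):
    return build_cuefeedback_design(run)


@pytest.fixture(scope="session")
def design_pool():
    """Shared pool of synthetic two-run subject designs (both models)."""
    return build_subject_designs(200, seed=2024)


@pytest.fixture
def rng():
    return np.random.default_rng(99)
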
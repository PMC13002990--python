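import warnings

import numpy as np
import pytest

import alcotwin as at


@pytest.fixture(scope="session")
def params() -> at.ParameterSet:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return at.ParameterSet()


@pytest.fixture(scope="session")
def male() -> at.Anthropometrics:
    return at.Anthropometrics("male", 106.6, 1.86, 28)


@pytest.fixture(scope="session")
def female() -> at.Anthropometrics:
    return at.Anthropometrics("female", 62.7, 1.69, 22)


@pytest.fixture(scope="session")
def wang_schedule() -> at.InputSchedule:
    return at.build_wang_protocol(106.6)


@pytest.fixture(scope="session")
def wang_trajectory(wang_schedule, male, params) -> at.Trajectory:
    return at.simulate(wang_schedule, male, params)


@pytest.fixture(scope="session")
def fast_options() -> at.SimOptions:
    # cheaper tolerances for tests that only need qualitative trajectories
    return at.SimOptions(rtol=1e-6, atol=1e-9)


@pytest.fixture(autouse=True)
def _quiet_bound_warnings():
    # two published Michaelis constants sit outside their own search bounds;
    # the validation warning is asserted explicitly in test_params
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="parameter Km")
        yield


def assert_monotone_nonincreasing(x: np.ndarray, tol: float = 0.0) -> None:
    assert np.all(np.diff(x) <= tol)
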
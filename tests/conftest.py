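import numpy as np
import pytest

from bdqsim import (
    CovariateSet,
    OmegaSet,
    ThetaSet,
    load_default_parameters,
    typical_parameters,
)


@pytest.fixture(scope="session")
def params():
    return load_default_parameters()


@pytest.fixture(scope="session")
def theta(params):
    return params.theta


@pytest.fixture(scope="session")
def omega(params):
    return params.omega


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def reference_cov():
    """Reference covariate category: all multipliers equal 1."""
    return CovariateSet("nonblack", "male", "MDR_TB")


@pytest.fixture(scope="session")
def typical_ds_male(theta):
    """Typical male nonblack DS-TB patient (the comparison population)."""
    return typical_parameters(theta, CovariateSet("nonblack", "male", "DS_TB"))


def make_theta(**overrides) -> ThetaSet:
    """A small, fast-kinetics parameter set for structural tests."""
    base = dict(
        apparent_clearance_typical=5.0,
        central_volume_typical=50.0,
        peripheral_volumes=(100.0, 200.0, 400.0),
        intercompartmental_clearances=(10.0, 4.0, 1.0),
        absorption_rate_path1=0.8,
        absorption_rate_path2=0.15,
        absorption_lag_path1=0.0,
        absorption_lag_path2=1.0,
        bioavailable_fraction_typical=1.0,
        fraction_to_path1_typical=0.7,
    )
    base.update(overrides)
    return ThetaSet(**base)


@pytest.fixture
def fast_theta():
    return make_theta()
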
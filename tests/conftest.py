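import numpy as np
import pytest

from recbcd_kinetics import ExperimentalCondition, ModelParameters
from recbcd_kinetics.synthetic import GroundTruth


@pytest.fixture(scope="session")
def truth():
    """Reference generator configuration (the session ground truth)."""
    return GroundTruth()


@pytest.fixture(scope="session")
def params(truth):
    return truth.params


@pytest.fixture
def base_condition():
    return ExperimentalCondition()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def reference_dataset(truth):
    """The reference multi-modality synthetic dataset (seed 1)."""
    from recbcd_kinetics.synthetic import gen_dataset

    ds, _ = gen_dataset(truth, seed=1)
    return ds


@pytest.fixture(scope="session")
def reference_fit(reference_dataset):
    """One converged global fit of the reference dataset, shared across
    the fitting and acceptance tests (it is the expensive step)."""
    from recbcd_kinetics import run_global_fit

    return run_global_fit(reference_dataset, n_starts=8, seed=1)


@pytest.fixture(scope="session")
def slow_params():
    """A deliberately slow-kinetics parameter set (cold-temperature regime)
    with the two binding pathways decoupled, used where tests must attribute
    a fitted phase to a specific pathway."""
    return ModelParameters(
        ks_on=2.0,
        ks_off=50.0,
        kw_on_intercept=0.1,
        kw_on_slope_ado=0.0,
        kw_off_intercept=20.0,
        kw_off_slope_nacl=0.0,
        ktr_fwd_intercept=0.0,
        ktr_fwd_slope_nacl=0.0,
        ktr_rev=0.0,
        coop_a=5.0,
        vmax=0.0,
    )
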
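import numpy as np
import pytest

import radialcontrast as rc


@pytest.fixture(scope="session")
def table1():
    return rc.load_table1()


@pytest.fixture(scope="session")
def small_kernel():
    """Compact DoG kernel (sigma_f=1, K=2) for fast semi-norm checks."""
    return rc.dog_kernel(rc.ReceptiveFieldProfile(0.0, 1.0, 2.0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210104)


def _curve(exp_id):
    config = rc.experiment_config(exp_id)
    return config, rc.run_experiment(config)


@pytest.fixture(scope="session")
def ka_run():
    return _curve("KA")


@pytest.fixture(scope="session")
def pl_run():
    return _curve("PL")


@pytest.fixture(scope="session")
def he_run():
    return _curve("HE")


@pytest.fixture(scope="session")
def pa_runs():
    return _curve("PA1"), _curve("PA5")
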
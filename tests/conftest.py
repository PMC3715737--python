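import numpy as np
import pytest

from orthoglm import reference_dataset, reference_regressors


@pytest.fixture(scope="session")
def ref_regs():
    """Z-scored RO and RPE regressors of the two-region reference scenario."""
    return reference_regressors()


@pytest.fixture(scope="session")
def fixture_ds():
    return reference_dataset(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_regressor_pair(rng, n=200, rho=0.6):
    """Two z-scored regressors with approximate correlation rho."""
    from orthoglm import Regressor, zscore

    a = rng.standard_normal(n)
    b = rho * a + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    ra = zscore(Regressor("A", a, dt=1.0))
    rb = zscore(Regressor("B", b, dt=1.0))
    return ra, rb
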
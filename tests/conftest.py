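import numpy as np
import pytest

from membranalysis import BilayerModel


@pytest.fixture
def control_model() -> BilayerModel:
    """Partly multilamellar control suspension (half unilamellar)."""
    return BilayerModel(
        z_H=20.1, sigma_H=2.5, rho_C=-1.2, sigma_C=4.0,
        d=65.8, N_layers=5, eta=0.1, N_UV=0.52, scale=1e-3, background=0.01,
    )


@pytest.fixture
def generic_init() -> BilayerModel:
    """A deliberately offset starting model for fit tests."""
    return BilayerModel(
        z_H=19.0, sigma_H=3.0, rho_C=-1.0, sigma_C=4.5,
        d=60.0, N_layers=4, eta=0.05, N_UV=0.5, scale=5e-4, background=0.005,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
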
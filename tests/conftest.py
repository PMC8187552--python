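import numpy as np
import pytest

from cnpbudget.hydrography import Cast
from cnpbudget.synthetic import ScenarioConfig, generate_cruise_dataset

STANDARD_DEPTHS = np.array([0.0, 10, 25, 50, 75, 100, 125, 150, 200])


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic scenario, shared across tests (seed 7)."""
    return generate_cruise_dataset(ScenarioConfig(seed=7))


@pytest.fixture
def simple_cast():
    """Warm stratified cast on the standard bottle grid."""
    z = STANDARD_DEPTHS
    temp = np.where(z <= 30.0, 29.0, 29.0 - (29.0 - 15.0) * (z - 30.0) / 170.0)
    par = 2000.0 * np.exp(-0.046 * z)
    return Cast(
        station="S1",
        date="2017-07-15",
        sst=29.0,
        depth=z,
        temperature=temp,
        salinity=np.full(z.size, 34.91),
        par=par,
        concentrations={
            "N+N": 1e-6 * np.array([20.0, 20, 20, 20, 20, 25, 600, 1200, 2500]),
            "PO4": 1e-6 * np.array([15.0, 15, 15, 15, 15, 18, 60, 110, 180]),
            "DIC": np.array([1.96, 1.96, 1.96, 1.961, 1.962, 1.963, 1.97, 1.98, 1.99]),
        },
    )
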
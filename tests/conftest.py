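import numpy as np
import pytest

from lvdp import ModelConfig, SimParams, simulate_patient
from lvdp.pipeline import record_from_synthetic
from lvdp.traces import Trace


@pytest.fixture(scope="session")
def config():
    return ModelConfig()


@pytest.fixture(scope="session")
def sim_params():
    return SimParams(
        psys=120.0, bmi=25.0, lars=35.0, tau_true=40.0, pre_a_true=8.0,
        edv=120.0, esv=50.0, hr=65.0, seed=42,
    )


@pytest.fixture(scope="session")
def sim_patient(sim_params):
    return simulate_patient(sim_params, patient_id="fixture")


@pytest.fixture(scope="session")
def sim_record(sim_patient):
    return record_from_synthetic(sim_patient)


def make_trace(t, v, kind):
    return Trace(np.asarray(t, float), np.asarray(v, float), kind)


@pytest.fixture
def linear_ramp_pressure():
    """4 -> 12 mmHg linear ramp over [0, 1] s."""
    t = np.linspace(0.0, 1.0, 101)
    return Trace(t, 4.0 + 8.0 * t, "pressure_mmHg")
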
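import numpy as np
import pytest

from ocupbpk import preset
from ocupbpk.scenario import SimulationSettings


def fast_settings(duration: float = 24.0) -> SimulationSettings:
    """Coarser grid / looser tolerances for property tests that run many sims."""
    return SimulationSettings(duration=duration, rtol=1e-7, atol=1e-12,
                              output_grid=np.linspace(0, duration, 145).tolist())


@pytest.fixture
def flm_ointment():
    return preset("flm_table1", variant="ointment", dose_ug=50.0)


@pytest.fixture
def flm_suspension():
    return preset("flm_table1", variant="suspension", dose_ug=50.0)


@pytest.fixture
def flm_solution():
    return preset("flm_table1", variant="solution", dose_ug=50.0)
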
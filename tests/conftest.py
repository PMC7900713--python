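import numpy as np
import pytest

from metaboscope.config import BiosensorModel
from metaboscope.scenarios import washout_washin_scenario, washout_cohort_params
from metaboscope.sim import simulate_cell_trace


@pytest.fixture(scope="session")
def biosensor() -> BiosensorModel:
    return BiosensorModel()


@pytest.fixture(scope="session")
def washout_cohort(biosensor):
    """20 noise-free wash-out/wash-in traces plus their generating parameters."""
    scen = washout_washin_scenario(n_cells=20, noise_sd=0.0, seed=1)
    cells = washout_cohort_params(20, seed=1, scen=scen)
    traces = [simulate_cell_trace(scen, biosensor, c) for c in cells]
    return scen, cells, traces
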
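import numpy as np
import pytest

from imcyto.cytometry import classify_cell_cycle
from imcyto.synthetic import SimulationParams, simulate_pulse_chase


def classify_timecourse(tables):
    """Label every chase table with the EdU threshold and G1 peak derived
    from the t=0 sample (the pulse-time reference), as an analysis would."""
    lab0 = classify_cell_cycle(tables[0][1])
    opts = {
        "edu_threshold": lab0.provenance["edu_threshold"],
        "g1_peak": lab0.provenance["g1_peak"],
    }
    return [(t, classify_cell_cycle(tbl, options=opts)) for t, tbl in tables]


@pytest.fixture(scope="session")
def headline_timecourse():
    """The reference pulse-chase simulation: (T_G1, T_S, T_G2M) =
    (6.0, 4.5, 3.5) h, 20-min pulse, hourly chase 0-20 h, 5000 cells."""
    params = SimulationParams(seed=7)
    tables, truth = simulate_pulse_chase(params)
    return params, tables, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
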
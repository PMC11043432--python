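import numpy as np
import pytest

from gridclock import clock_design as cd
from gridclock import synthetic_data as sd


@pytest.fixture(scope="session")
def session_design():
    return cd.build_session(seed=7)


@pytest.fixture(scope="session")
def noiseless_subject(session_design):
    """Planted 6-fold tuning at 23 deg, no noise, no voxel heterogeneity."""
    return sd.simulate_subject(
        session_design,
        roi_tuning=sd.TuningModel(fold_n=6, phase_deg=23.0, gain=0.03),
        noise=sd.NoiseModel(sigma=0.0, ar1_rho=0.0, drift_amplitudes=()),
        config=sd.SimulationConfig(
            n_voxels=4, phase_jitter_kappa=None, amplitude_sigma=0.0
        ),
        seed=1,
    )
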
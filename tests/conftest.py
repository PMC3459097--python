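import numpy as np
import pytest

from neohrf.hrf import PRESET_METRICS, get_preset
from neohrf.synth import Geometry, NoiseSpec, make_event_design, simulate_bold


@pytest.fixture(scope="session")
def event_design():
    """The study's event-related acquisition: TR 0.5 s, 1000 volumes,
    1 s stimulus, 40.5 s inter-stimulus interval (12 epochs)."""
    return make_event_design(0.5, 1000, 1.0, 40.5)


@pytest.fixture(scope="session")
def presets():
    return {g: get_preset(g) for g in PRESET_METRICS}


@pytest.fixture(scope="session")
def noiseless_adult_run(event_design):
    """Single-active-voxel noiseless run with the adult preset at 1%."""
    return simulate_bold(
        event_design,
        get_preset("adult"),
        Geometry(shape=(4, 4, 2), active_radius=0.5),
        NoiseSpec(white_sd=0.0),
        truth_amplitude=1.0,
        seed=0,
    )


def active_series(run) -> np.ndarray:
    """Time series of the first active voxel of a synthetic run."""
    return run.volumes[run.truth_mask][0]
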
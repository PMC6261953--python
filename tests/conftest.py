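import numpy as np
import pytest

from thetaoff import CellSpec, SessionConfig, simulate_session
from thetaoff.core import RegularTimeSeries


@pytest.fixture(scope="session")
def small_session():
    """120-s session at reduced LFP rate with two cells of each class."""
    config = SessionConfig(duration_s=120.0, lfp_rate_hz=2000.0, seed=42,
                           ripple_rate_hz=0.2)
    specs = [
        CellSpec(cell_class="theta_off", cell_id="off0"),
        CellSpec(cell_class="theta_off", cell_id="off1"),
        CellSpec(
            cell_class="theta_on",
            rate_locomotion_hz=0.4,
            rate_immobility_hz=0.05,
            cell_id="on0",
        ),
        CellSpec(
            cell_class="theta_on",
            rate_locomotion_hz=0.4,
            rate_immobility_hz=0.05,
            cell_id="on1",
        ),
    ]
    return simulate_session(config, specs)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_series(data, rate_hz, **kwargs):
    return RegularTimeSeries(np.asarray(data, dtype=float), rate_hz, **kwargs)
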
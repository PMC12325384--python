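import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lfpdecode as L
from lfpdecode.features import BANDS

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def desk_grid():
    return L.make_grid(5, 5, True)


@pytest.fixture(scope="session")
def desk_schedule():
    return L.TrialSchedule.make(repetitions=3, tone_duration_s=11.0,
                                gap_duration_s=2.0, seed=1)


@pytest.fixture(scope="session")
def desk_session(desk_grid, desk_schedule):
    """One reduced-scale synthetic session shared across tests."""
    return L.simulate_session(desk_grid, desk_schedule, L.GeneratorParams(), 7)


@pytest.fixture(scope="session")
def desk_mask(desk_session):
    return L.screen_session(desk_session)


@pytest.fixture(scope="session")
def desk_windows(desk_session, desk_mask):
    return L.extract_analysis_windows(desk_session, desk_mask, n_per_label=21)


@pytest.fixture(scope="session")
def theta_power_table(desk_session, desk_windows):
    return L.build_feature_table(desk_session, desk_windows, BANDS["theta"], "power")


@pytest.fixture(scope="session")
def hg_plv_table(desk_session, desk_windows):
    return L.build_feature_table(desk_session, desk_windows,
                                 BANDS["high-gamma"], "plv")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
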
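import numpy as np
import pandas as pd
import pytest

from synthpanel import FixtureConfig, compute_acwr, generate_fixture


@pytest.fixture(scope="session")
def default_panel():
    """The default 34 x 120 fixture panel, with ACWR, shared across tests."""
    return compute_acwr(generate_fixture(FixtureConfig(seed=1)))


@pytest.fixture(scope="session")
def small_panel():
    """A small, fast panel (8 players x 30 weeks) for pipeline tests."""
    return compute_acwr(generate_fixture(FixtureConfig(n_players=8, n_weeks=30, seed=5)))


@pytest.fixture()
def tiny_panel():
    """A hand-written 2-player panel with known values."""
    return pd.DataFrame(
        {
            "PlayerID": [1] * 5 + [2] * 5,
            "WeekID": list(range(1, 6)) * 2,
            "AcuteLoad": [100.0, 200.0, 300.0, 400.0, 500.0, 50.0, 60.0, 70.0, 80.0, 90.0],
            "ChronicLoad": [np.nan] * 10,
            "Injury": [0, 0, 1, 0, 0, 0, 0, 0, 0, 1],
        }
    )
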
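import numpy as np
import pytest
from shapely.geometry import Polygon

import phre


@pytest.fixture(scope="session")
def half_plane_land():
    """Land occupying y >= 0, as a large rectangle; water below."""
    return phre.LandPolygons(
        Polygon([(-1e6, 0), (1e6, 0), (1e6, 1e6), (-1e6, 1e6)])
    )


@pytest.fixture(scope="session")
def straight_scenario():
    return phre.make_scenario(phre.CoastScenario(kind="straight"))


@pytest.fixture(scope="session")
def sinusoidal_scenario():
    return phre.make_scenario(phre.CoastScenario(kind="sinusoidal"))


@pytest.fixture(scope="session")
def peninsula_scenario():
    return phre.make_scenario(phre.CoastScenario(kind="peninsula"))


@pytest.fixture(scope="session")
def straight_sightings(straight_scenario):
    """300 sightings from a single-mode movement model on the straight coast."""
    model = phre.MovementModel(means=(30.0,), sds=(5.0,), n=300, seed=7)
    sightings, truth = phre.simulate_sightings(model, straight_scenario)
    return sightings, truth, model


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
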
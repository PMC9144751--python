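import numpy as np
import pytest

from phenoprime import GrowthScenario, make_grid_layout, render_plate, simulate_growth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scenario():
    """A reduced plate design: 6 plants/group, default biology."""
    return GrowthScenario(n_plants_per_group=6, seed=42)


@pytest.fixture
def noiseless_scenario():
    return GrowthScenario(
        n_plants_per_group=2, noise_cv=0.0, gli_sd=0.0, seed=0
    )


@pytest.fixture(scope="session")
def rendered_scene():
    """A 2x3 plate with five plants of known area/greenness and one empty well."""
    layout = make_grid_layout(2, 3)
    entries = [
        (0, 500, 0.40),
        (1, 800, 0.35),
        (2, 300, 0.45),
        (3, 1200, 0.40),
        (4, 650, 0.30),
        (5, 0, 0.40),
    ]
    scene = render_plate(entries, layout, seed=7)
    return scene, entries
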
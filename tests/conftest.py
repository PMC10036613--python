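import numpy as np
import pytest

from gazestrat.games import Game, generate_battery
from gazestrat.render import build_layout
from gazestrat.synth import GeneratorConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def layout():
    return build_layout()


@pytest.fixture(scope="session")
def config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def example_game():
    """The worked game: unique NE (Middle, Left), column dominant Left,
    naive Bottom, coordination Middle."""
    return Game(
        game_id="example",
        row_payoffs=[[3, 9, 2], [7, 1, 1], [2, 8, 6]],
        col_payoffs=[[5, 1, 0], [4, 2, 1], [6, 3, 2]],
        category="DO",
    )


@pytest.fixture(scope="session")
def battery():
    return generate_battery(np.random.default_rng(99))


@pytest.fixture(scope="session")
def small_cohort(battery, layout):
    """30 participants x 10 games of default-calibration synthetic trials."""
    return simulate_dataset(
        30, battery, GeneratorConfig(), np.random.default_rng(7), layout
    )
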
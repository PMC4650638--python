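import numpy as np
import pytest

from invasim.agents import EnergyParams, ModeParams
from invasim.engine import SimConfig
from invasim.interactions import InteractionParams
from invasim.maze import Disc, MazeGenParams, MazeGrid


@pytest.fixture
def small_maze():
    """20x20 open arena (80x80 world units) with a wall bar in the middle."""
    wall = np.zeros((20, 20))
    wall[:, 10] = 1.0  # horizontal bar at y in [40, 44)
    wall[4:6, 10] = 0.0  # gap
    return MazeGrid(wall, 4.0, (80.0, 80.0),
                    start=Disc((12.0, 12.0), 6.0), target=Disc((68.0, 68.0), 6.0))


@pytest.fixture
def open_maze():
    wall = np.zeros((20, 20))
    return MazeGrid(wall, 4.0, (80.0, 80.0),
                    start=Disc((12.0, 12.0), 6.0), target=Disc((68.0, 68.0), 6.0))


def tiny_config(**kw):
    """Small, fast run configuration for engine tests."""
    defaults = dict(
        seed=1,
        n_agents=10,
        mes_fraction=0.5,
        t_max=100.0,
        maze=MazeGenParams(wall_fraction=0.2, pore_scale=60.0, seed=3),
        world_extent=(200.0, 200.0),
        cell_size=4.0,
        start_center=(30.0, 30.0),
        start_radius=15.0,
        target_center=(170.0, 170.0),
        target_radius=15.0,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
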
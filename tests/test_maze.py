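import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from invasim.maze import (Disc, MazeGenParams, MazeGrid, degrade,
                          generate_maze, load_maze, move_with_collision,
                          wall_normal)

START = Disc((12.0, 12.0), 6.0)
TARGET = Disc((68.0, 68.0), 6.0)


class TestLoadMaze:
    def test_text_grid_direct_mapping(self):
        maze = load_maze("##\n..", "text", start=Disc((0.5, 0.5), 0.1),
                         target=Disc((1.5, 0.5), 0.1), world_extent=(2.0, 2.0),
                         initial_wall_mass=1.0)
        # first text row is the top of the world
        assert maze.wall_mass[0, 1] == 1.0 and maze.wall_mass[1, 1] == 1.0
        assert maze.wall_mass[0, 0] == 0.0 and maze.wall_mass[1, 0] == 0.0

    def test_all_open(self):
        maze = load_maze("....\n....\n....\n....", "text", start=START,
                         target=TARGET, world_extent=(80.0, 80.0))
        assert maze.total_mass() == 0.0

    def test_text_roundtrip(self):
        params = MazeGenParams(seed=7)
        maze = generate_maze(params, start=START, target=TARGET)
        text = maze.to_text()
        maze2 = load_maze(text, "text", start=START, target=TARGET,
                          world_extent=maze.world_extent)
        assert np.array_equal(maze.wall_mass > 0, maze2.wall_mass > 0)
        assert maze2.to_text() == text

    def test_image_roundtrip(self, tmp_path):
        maze = generate_maze(MazeGenParams(seed=11), start=START, target=TARGET)
        pgm = tmp_path / "maze.pgm"
        maze.to_pgm(str(pgm))
        maze2 = load_maze(str(pgm), "image", start=START, target=TARGET,
                          world_extent=maze.world_extent)
        assert np.array_equal(maze.wall_mass > 0, maze2.wall_mass > 0)

    def test_non_rectangular_rejected(self):
        with pytest.raises(ValueError):
            load_maze("##\n#", "text", start=Disc((0.5, 0.5), 0.1),
                      target=Disc((1.5, 0.5), 0.1), world_extent=(2.0, 2.0))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            load_maze("", "text", start=START, target=TARGET)

    def test_start_outside_domain_rejected(self):
        with pytest.raises(ValueError):
            load_maze("..\n..", "text", start=Disc((500.0, 500.0), 1.0),
                      target=Disc((1.5, 0.5), 0.1), world_extent=(2.0, 2.0))


class TestGenerateMaze:
    def test_zero_wall_fraction_empty(self):
        maze = generate_maze(MazeGenParams(wall_fraction=0.0, seed=1),
                             start=START, target=TARGET)
        assert maze.total_mass() == 0.0

    def test_seed_reproducible_bit_exact(self):
        a = generate_maze(MazeGenParams(seed=42), start=START, target=TARGET)
        b = generate_maze(MazeGenParams(seed=42), start=START, target=TARGET)
        assert np.array_equal(a.wall_mass, b.wall_mass)

    def test_seeds_differ(self):
        a = generate_maze(MazeGenParams(seed=1), start=START, target=TARGET)
        b = generate_maze(MazeGenParams(seed=2), start=START, target=TARGET)
        assert not np.array_equal(a.wall_mass, b.wall_mass)

    @pytest.mark.parametrize("wf", [0.2, 0.3])
    def test_wall_fraction_targeted(self, wf):
        # tiny carve discs so the measured fraction reflects the raw field
        params = MazeGenParams(wall_fraction=wf, seed=5)
        maze = generate_maze(params, start=Disc((2.0, 2.0), 1.0),
                             target=Disc((798.0, 798.0), 1.0))
        assert abs(maze.wall_fraction() - wf) < 0.05

    def test_start_and_target_carved_open(self):
        maze = generate_maze(MazeGenParams(seed=9), start=START, target=TARGET)
        for disc in (maze.start, maze.target):
            assert not maze.blocked(disc.center)


class TestWallNormal:
    def _grid(self, wall):
        return MazeGrid(wall, 1.0, (5.0, 5.0), start=Disc((0.5, 4.5), 0.2),
                        target=Disc((4.5, 4.5), 0.2))

    def test_flat_wall_below(self):
        wall = np.zeros((5, 5))
        wall[:, 0] = 1.0
        maze = self._grid(wall)
        n = wall_normal(maze, (2.5, 0.5))
        assert np.allclose(n, [0.0, 1.0])

    def test_flat_wall_right(self):
        wall = np.zeros((5, 5))
        wall[4, :] = 1.0
        maze = self._grid(wall)
        n = wall_normal(maze, (4.5, 2.5))
        assert np.allclose(n, [-1.0, 0.0])

    def test_inner_corner_diagonal(self):
        # 90-degree inner corner: wall column to the right, wall row below;
        # the 3x3 occupancy stencil around the corner cell sums to (2, -2)
        wall = np.zeros((5, 5))
        wall[4, :] = 1.0
        wall[:, 0] = 1.0
        maze = self._grid(wall)
        n = wall_normal(maze, (3.5, 1.5))
        assert np.allclose(n, np.array([-1.0, 1.0]) / np.sqrt(2.0))


class TestMoveWithCollision:
    def test_free_motion(self, open_maze):
        new, contact = move_with_collision(open_maze, (10.0, 10.0), (2.0, 1.0), 1.0)
        assert np.allclose(new, [12.0, 11.0]) and contact is None

    def test_rest(self, open_maze):
        new, contact = move_with_collision(open_maze, (10.0, 10.0), (0.0, 0.0), 1.0)
        assert np.allclose(new, [10.0, 10.0]) and contact is None

    def test_stops_at_wall_with_outward_normal(self, small_maze):
        # wall band is y in [40, 44); approach from below going straight up
        new, normal = move_with_collision(small_maze, (50.0, 38.0), (0.0, 10.0), 1.0)
        assert new[1] < 40.0
        assert 40.0 - new[1] <= small_maze.cell_size / 2
        assert not small_maze.blocked(new)
        assert normal is not None and normal[1] < 0

    def test_matches_dense_substep_oracle(self, small_maze):
        rng = np.random.default_rng(7)
        cs = small_maze.cell_size
        for _ in range(100):
            pos = rng.uniform(4, 76, size=2)
            if small_maze.blocked(pos):
                continue
            vel = rng.normal(0, 5, size=2)
            new, contact = move_with_collision(small_maze, pos, vel, 1.0)
            # oracle: walk the segment in steps of cell_size/100
            disp = np.asarray(vel)
            L = np.linalg.norm(disp)
            nsub = max(1, int(np.ceil(L / (cs / 100))))
            p = np.asarray(pos, float)
            hit = False
            for k in range(nsub):
                cand = np.asarray(pos) + (k + 1) / nsub * disp
                if small_maze.blocked(cand):
                    hit = True
                    break
                p = cand
            assert hit == (contact is not None)
            assert np.linalg.norm(np.asarray(new) - p) <= cs / 10
            assert not small_maze.blocked(new)

    def test_domain_boundary_blocks(self, open_maze):
        new, normal = move_with_collision(open_maze, (78.0, 40.0), (10.0, 0.0), 1.0)
        assert new[0] < 80.0 and normal is not None
        assert normal[0] < 0

    @settings(max_examples=50, deadline=None)
    @given(x=st.floats(2, 78), y=st.floats(2, 78),
           vx=st.floats(-20, 20), vy=st.floats(-20, 20))
    def test_never_ends_in_wall(self, x, y, vx, vy):
        wall = np.zeros((20, 20))
        wall[:, 10] = 1.0
        wall[4:6, 10] = 0.0
        maze = MazeGrid(wall, 4.0, (80.0, 80.0),
                        start=Disc((12.0, 12.0), 6.0),
                        target=Disc((68.0, 68.0), 6.0))
        if maze.blocked((x, y)):
            return
        new, _ = move_with_collision(maze, (x, y), (vx, vy), 1.0)
        assert not maze.blocked(new)

    def test_pos_in_wall_rejected(self, small_maze):
        with pytest.raises(ValueError):
            move_with_collision(small_maze, (50.0, 42.0), (1.0, 0.0), 1.0)


class TestDegrade:
    def test_full_degradation_opens_cell(self, small_maze):
        removed = degrade(small_maze, [(8, 10)], 5.0)
        assert removed == 1.0
        assert small_maze.wall_mass[8, 10] == 0.0

    def test_zero_amount_noop(self, small_maze):
        before = small_maze.wall_mass.copy()
        removed = degrade(small_maze, [(8, 10)], 0.0)
        assert removed == 0.0 and np.array_equal(small_maze.wall_mass, before)

    def test_mass_bookkeeping(self, small_maze):
        before = small_maze.total_mass()
        cells = [(7, 10), (8, 10), (9, 10), (3, 3)]
        removed = degrade(small_maze, cells, 0.4)
        assert np.isclose(before - small_maze.total_mass(), removed)
        assert np.all(small_maze.wall_mass >= 0)

    def test_out_of_raster_rejected(self, small_maze):
        with pytest.raises(IndexError):
            degrade(small_maze, [(100, 0)], 1.0)
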
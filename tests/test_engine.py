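import numpy as np
import pytest

from conftest import tiny_config
from invasim import _kernel
from invasim.agents import EnergyParams, ModeParams, stationary_energy
from invasim.engine import (SimConfig, build_world, derive_seed, run, step,
                            sweep)
from invasim.interactions import InteractionParams
from invasim.maze import MazeGenParams


def _noiseless_modes():
    return dict(amoeboid=ModeParams(gamma=1.0, sigma=1e-12, can_degrade=False),
                mesenchymal=ModeParams(gamma=2.0, sigma=0.0, can_degrade=True))


class TestDeterminism:
    def test_identical_seed_bit_identical(self):
        cfg = tiny_config(seed=77, interaction=InteractionParams(mode="constant"))
        r1 = run(cfg)
        r2 = run(cfg)
        assert np.array_equal(r1.status, r2.status)
        assert np.array_equal(r1.arrival_time, r2.arrival_time, equal_nan=True)
        assert r1.wall_mass_removed == r2.wall_mass_removed
        assert r1.trajectories.equals(r2.trajectories)

    def test_different_seed_differs(self):
        r1 = run(tiny_config(seed=1))
        r2 = run(tiny_config(seed=2))
        assert not r1.trajectories.equals(r2.trajectories)

    def test_interaction_none_equals_disarmed_constant(self):
        # constant interaction with w=0 and k_rep=0 must reproduce the
        # none-mode dynamics bit-exactly (no RNG stream divergence)
        base = tiny_config(seed=9)
        off = tiny_config(seed=9, interaction=InteractionParams(
            mode="constant", w_const=0.0, k_rep=0.0))
        ra, rb = run(base), run(off)
        assert ra.trajectories.equals(rb.trajectories)


class TestKernelMatchesReferenceStep:
    def test_trajectory_agreement_deterministic_case(self):
        cfg = tiny_config(seed=5, n_agents=12, t_max=50.0,
                          interaction=InteractionParams(mode="constant"),
                          **_noiseless_modes())
        # python reference path
        wp = build_world(cfg)
        rng = np.random.default_rng(0)
        for _ in range(cfg.n_steps()):
            step(wp, cfg, rng)
        # compiled path
        wk = build_world(cfg)
        _kernel.seed(1)
        ia = cfg.effective_interaction()
        m = wk.maze
        bad = _kernel.advance(
            m.wall_mass, m.cell_size, m.world_extent[0], m.world_extent[1],
            m.target.center[0], m.target.center[1], m.target.radius,
            wk.pos, wk.vel, wk.e, wk.e_bar, wk.heading, wk.mode, wk.phase,
            wk.next_reor, wk.stuck, wk.status, wk.arrival, 0, cfg.n_steps(),
            cfg.dt,
            cfg.tau_reorient, cfg.tau_stuck, cfg.energy.eta, cfg.energy.q,
            cfg.energy.c, cfg.energy.k_w, cfg.energy.reach,
            cfg.energy.max_deg_mass, cfg.amoeboid.gamma, cfg.mesenchymal.gamma,
            cfg.amoeboid.sigma, cfg.mesenchymal.sigma, _kernel.IMODE_CONST,
            ia.r_rep, ia.r_align, ia.k_rep, ia.w_const, ia.w0, ia.e_half,
            ia.n_hill, ia.tau_w, wk.ledger)
        assert bad == -1
        assert np.allclose(wp.pos, wk.pos, atol=1e-9)
        assert np.allclose(wp.vel, wk.vel, atol=1e-9)
        assert np.allclose(wp.e, wk.e, atol=1e-9)
        assert np.allclose(wp.maze.wall_mass, wk.maze.wall_mass)
        assert np.allclose(wp.ledger, wk.ledger, atol=1e-9)


class TestFreeSpaceKinematics:
    def test_straight_line_and_arrival(self):
        cfg = tiny_config(seed=3, n_agents=1, mes_fraction=0.0, t_max=600.0,
                          maze=MazeGenParams(wall_fraction=0.0, seed=1),
                          start_radius=0.5, energy=EnergyParams(q=1.0),
                          **_noiseless_modes())
        res = run(cfg)
        assert res.successes("amoeboid") == 1
        traj = res.trajectories
        active = traj[traj.status == "active"]
        # noiseless cue: trajectory stays on the start->target line
        p0 = np.array(cfg.start_center)
        p1 = np.array(cfg.target_center)
        d = (p1 - p0) / np.linalg.norm(p1 - p0)
        rel = active[["x", "y"]].to_numpy() - p0
        cross = np.abs(rel[:, 0] * d[1] - rel[:, 1] * d[0])
        assert cross.max() < 1.0

    def test_stationary_energy_within_one_percent(self):
        # noiseless, no walls, no interaction, no reorientation events
        cfg = tiny_config(seed=11, n_agents=1, mes_fraction=0.0, t_max=400.0,
                          maze=MazeGenParams(wall_fraction=0.0, seed=1),
                          world_extent=(4000.0, 4000.0), cell_size=20.0,
                          start_center=(200.0, 200.0), start_radius=1.0,
                          target_center=(3800.0, 3800.0), target_radius=10.0,
                          tau_reorient=1e9, energy=EnergyParams(q=1.0),
                          **_noiseless_modes())
        res = run(cfg)
        e_star = stationary_energy(1.0, cfg.energy.c, cfg.energy.eta,
                                   cfg.amoeboid.gamma)
        trace = res.energy_trace
        late = trace[trace.t > 200.0]["mean_e"]
        assert np.all(np.abs(late - e_star) / e_star < 0.01)


class TestRunContract:
    def test_zero_time_no_success(self):
        res = run(tiny_config(seed=4, t_max=0.0))
        assert res.successes("mesenchymal") == 0 and res.successes("amoeboid") == 0

    def test_population_split_report(self):
        cfg = tiny_config(seed=6, n_agents=50, mes_fraction=0.8, t_max=5.0)
        res = run(cfg)
        assert res.population("mesenchymal") == 40
        assert res.population("amoeboid") == 10

    def test_energy_bookkeeping_identity(self):
        cfg = tiny_config(seed=8, t_max=200.0,
                          interaction=InteractionParams(mode="dynamic"))
        res = run(cfg)
        led = res.energy_ledger
        world = build_world(cfg)  # same seed: identical initial energies
        e_init_sum = world.e.sum()
        final = res.trajectories[res.trajectories.t ==
                                 res.trajectories.t.max()]["e"].sum()
        budget = (led["intake"] - led["dissipation"] - led["mechanical"]
                  - led["proteolysis"] + led["clamped"])
        assert abs((final - e_init_sum) - budget) < 1e-6 * led["n_steps"]

    def test_energy_never_negative(self):
        res = run(tiny_config(seed=13, energy=EnergyParams(q=0.2), t_max=150.0))
        assert (res.trajectories["e"] >= 0).all()

    def test_wall_mass_monotone_and_ledger_consistent(self):
        cfg = tiny_config(seed=15, mes_fraction=1.0, t_max=300.0,
                          energy=EnergyParams(q=1.0))
        maze_before = build_world(cfg).maze.total_mass()
        res = run(cfg)
        assert res.wall_mass_removed >= 0
        assert res.wall_mass_removed <= maze_before
        spent = res.energy_ledger["proteolysis"]
        assert np.isclose(spent, cfg.energy.k_w * res.wall_mass_removed)

    def test_amoeboids_never_degrade(self):
        res = run(tiny_config(seed=16, mes_fraction=0.0, t_max=300.0))
        assert res.wall_mass_removed == 0.0
        assert res.energy_ledger["proteolysis"] == 0.0

    def test_arrived_agents_frozen(self):
        cfg = tiny_config(seed=17, t_max=400.0,
                          maze=MazeGenParams(wall_fraction=0.0, seed=1))
        res = run(cfg)
        traj = res.trajectories
        for aid in traj.id.unique():
            rows = traj[(traj.id == aid) & (traj.status == "arrived")]
            if len(rows) > 1:
                assert rows["x"].nunique() == 1 and rows["y"].nunique() == 1
                assert rows["e"].nunique() == 1

    def test_amoeboid_positions_never_in_walls(self):
        cfg = tiny_config(seed=18, mes_fraction=0.0, t_max=200.0)
        world = build_world(cfg)
        res = run(cfg)
        traj = res.trajectories
        act = traj[traj.status == "active"]
        for x, y in act[["x", "y"]].to_numpy():
            assert not world.maze.blocked((x, y))


class TestSweep:
    def test_degenerate_grid_equals_single_run(self):
        base = tiny_config(seed=0, t_max=150.0)
        summary = sweep(base, [0.5], [1.0], 1, seed0=42)
        runs = summary.attrs["runs"]
        cfg = tiny_config(seed=int(runs.seed.iloc[0]), mes_fraction=0.5,
                          maze=MazeGenParams(wall_fraction=0.2, pore_scale=60.0,
                                             seed=derive_seed(42, 9999, 0)),
                          t_max=150.0)
        res = run(cfg, record_trajectories=False)
        for mode in ("mesenchymal", "amoeboid"):
            got = summary[summary["mode"] == mode]["mean_success"].iloc[0]
            pop = res.population(mode)
            assert got == pytest.approx(res.successes(mode) / pop)

    def test_summary_shape_and_bounds(self):
        base = tiny_config(seed=0, t_max=50.0)
        summary = sweep(base, [0.2, 0.5], [0.8, 1.0], 2, seed0=7)
        assert len(summary) == 2 * 2 * 2  # modes x fractions x q
        assert summary["mean_success"].between(0, 1).all()
        assert (summary["se"] >= 0).all()
        assert set(summary["n_reps"]) == {2}

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep(tiny_config(seed=0), [], [1.0], 1, seed0=1)


class TestConfig:
    def test_dict_roundtrip(self):
        cfg = tiny_config(seed=123, interaction=InteractionParams(mode="dynamic"))
        cfg2 = SimConfig.from_dict(cfg.to_dict())
        assert cfg2 == cfg

    def test_validation(self):
        with pytest.raises(ValueError):
            tiny_config(seed=1, dt=0.0)
        with pytest.raises(ValueError):
            tiny_config(seed=1, n_agents=0)
        with pytest.raises(ValueError):
            tiny_config(seed=1, mes_fraction=1.5)
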
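"""Simulation engine: configuration, time stepping, runs and parameter sweeps.

A :class:`SimConfig` bundles every physical and numerical parameter plus the
seed; :func:`run` integrates one realization and returns a :class:`SimResult`
with sampled trajectories, arrival times, per-mode success counts and an
energy ledger; :func:`sweep` runs replicate ensembles over grids of the
mesenchymal fraction and the energy intake rate q.

Two integration paths share one contract: :func:`step` is the readable
pure-Python reference (built from the ``agents``/``interactions``/``maze``
operations), while :func:`run` dispatches to a compiled kernel
(:mod:`invasim._kernel`) for production ensembles.  Both use semi-implicit
Euler with simultaneous neighbor evaluation, so results do not depend on
agent ordering, and a single seeded generator fixes everything: maze,
initial placement, heading noise.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernel
from .agents import (AMOEBOID, MESENCHYMAL, MODE_NAMES, EnergyParams,
                     ModeParams, attempt_degradation, AgentState,
                     draw_heading, init_population, stationary_energy)
from .interactions import InteractionParams, alignment_update, repulsion_force, w_of_e
from .maze import Disc, MazeGenParams, MazeGrid, generate_maze, load_maze, \
    move_with_collision

__all__ = ["SimConfig", "SimResult", "World", "build_world", "step", "run",
           "sweep", "derive_seed"]

logger = logging.getLogger(__name__)

_IMODE_CODE = {"none": _kernel.IMODE_NONE, "constant": _kernel.IMODE_CONST,
               "dynamic": _kernel.IMODE_DYNAMIC}

def derive_seed(*parts: int) -> int:
    """Deterministic sub-seed (< 2^31) from integer parts."""
    ss = np.random.SeedSequence([int(p) for p in parts])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class SimConfig:
    """Complete run configuration (all world units / model units).

    The maze is either procedurally generated (``maze``: MazeGenParams) or
    loaded from ``maze_file`` (image or '#'/'.' text; ``maze_format`` to
    force).  ``seed`` is required — there is no wall-clock default.
    """

    seed: int
    mes_fraction: float = 0.5
    n_agents: int = 50
    energy: EnergyParams = field(default_factory=lambda: EnergyParams(q=1.0))
    amoeboid: ModeParams = field(default_factory=lambda: ModeParams(
        gamma=1.0, sigma=1.0, can_degrade=False))
    mesenchymal: ModeParams = field(default_factory=lambda: ModeParams(
        gamma=2.0, sigma=0.2, can_degrade=True))
    interaction: InteractionParams = field(default_factory=InteractionParams)
    maze: MazeGenParams | None = field(default_factory=MazeGenParams)
    maze_file: str | None = None
    maze_format: str | None = None
    world_extent: tuple[float, float] = (800.0, 800.0)
    cell_size: float = 4.0
    initial_wall_mass: float = 1.0
    start_center: tuple[float, float] = (40.0, 40.0)
    start_radius: float = 25.0
    target_center: tuple[float, float] = (760.0, 760.0)
    target_radius: float = 25.0
    dt: float = 0.05
    t_max: float = 5000.0
    tau_reorient: float = 10.0
    tau_stuck: float = 10.0
    # initial depot level; None = each mode's free-space stationary energy
    # at the run's intake rate (agents start adapted to their medium)
    e_init: float | None = None
    sample_stride: int = 100  # steps between trajectory samples

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed must be set explicitly")
        if self.dt <= 0 or self.t_max < 0:
            raise ValueError("dt must be > 0 and t_max >= 0")
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if not 0.0 <= self.mes_fraction <= 1.0:
            raise ValueError("mes_fraction must be in [0, 1]")
        if self.mesenchymal.gamma <= self.amoeboid.gamma:
            raise ValueError("gamma_M must exceed gamma_A")
        if self.amoeboid.sigma <= self.mesenchymal.sigma:
            raise ValueError("sigma_A must exceed sigma_M")

    def effective_interaction(self) -> InteractionParams:
        """Interaction params with e_half resolved: default is the free-space
        amoeboid stationary energy at q = 0.6, the top of the stressed
        intake range (the switch engages below it)."""
        ia = self.interaction
        if ia.e_half is None:
            e_half = stationary_energy(0.6, self.energy.c, self.energy.eta,
                                       self.amoeboid.gamma)
            ia = replace(ia, e_half=e_half)
        return ia

    def n_steps(self) -> int:
        return int(round(self.t_max / self.dt))

    # -- (de)serialization: JSON-compatible key/value tree ------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "energy" in d and isinstance(d["energy"], dict):
            d["energy"] = EnergyParams(**d["energy"])
        for key in ("amoeboid", "mesenchymal"):
            if key in d and isinstance(d[key], dict):
                d[key] = ModeParams(**d[key])
        if "interaction" in d and isinstance(d["interaction"], dict):
            d["interaction"] = InteractionParams(**d["interaction"])
        if d.get("maze") is not None and isinstance(d["maze"], dict):
            d["maze"] = MazeGenParams(**d["maze"])
        for key in ("world_extent", "start_center", "target_center"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class World:
    """Mutable simulation state: the maze plus per-agent arrays."""

    maze: MazeGrid
    pos: np.ndarray
    vel: np.ndarray
    e: np.ndarray
    e_bar: np.ndarray  # low-pass-filtered depot level (stress read-out)
    heading: np.ndarray
    mode: np.ndarray
    phase: np.ndarray
    next_reor: np.ndarray
    stuck: np.ndarray
    status: np.ndarray
    arrival: np.ndarray
    step_count: int = 0
    ledger: np.ndarray = field(
        default_factory=lambda: np.zeros(_kernel.N_LEDGER))

    @property
    def n(self) -> int:
        return self.pos.shape[0]

    def active(self) -> np.ndarray:
        return self.status == 0


def make_maze(config: SimConfig) -> MazeGrid:
    start = Disc(config.start_center, config.start_radius)
    target = Disc(config.target_center, config.target_radius)
    if config.maze_file is not None:
        return load_maze(config.maze_file, config.maze_format, start=start,
                         target=target, world_extent=config.world_extent,
                         initial_wall_mass=config.initial_wall_mass)
    if config.maze is None:
        raise ValueError("config needs either maze generation params or maze_file")
    return generate_maze(config.maze, config.world_extent, start, target,
                         config.cell_size, config.initial_wall_mass)


def initial_energies(config: SimConfig, modes: np.ndarray) -> np.ndarray:
    """Per-agent starting depot levels: the configured constant, or each
    mode's free-space stationary energy at the run's intake rate."""
    if config.e_init is not None:
        return np.full(len(modes), float(config.e_init))
    en = config.energy
    levels = {m: stationary_energy(en.q, en.c, en.eta, g)
              for m, g in ((AMOEBOID, config.amoeboid.gamma),
                           (MESENCHYMAL, config.mesenchymal.gamma))}
    return np.array([levels[int(m)] for m in modes])


def build_world(config: SimConfig) -> World:
    """Generate/load the maze and place the initial population."""
    s_init = derive_seed(config.seed, 1)
    rng = np.random.default_rng(s_init)
    maze = make_maze(config)
    agents = init_population(config.n_agents, config.mes_fraction, maze,
                             1.0, rng,
                             sigma_mes=config.mesenchymal.sigma,
                             sigma_amo=config.amoeboid.sigma,
                             tau_reorient=config.tau_reorient)
    n = len(agents)
    modes = np.array([a.mode for a in agents], dtype=np.int8)
    e0 = initial_energies(config, modes)
    world = World(
        maze=maze,
        pos=np.array([a.r for a in agents]),
        vel=np.zeros((n, 2)),
        e=e0.astype(np.float64),
        e_bar=e0.astype(np.float64),
        heading=np.array([a.heading for a in agents]),
        mode=modes,
        phase=np.ones(n, dtype=np.int8),
        next_reor=np.full(n, config.tau_reorient, dtype=np.float64),
        stuck=np.zeros(n),
        status=np.zeros(n, dtype=np.int8),
        arrival=np.full(n, np.nan),
    )
    return world


# ---------------------------------------------------------------------------
# Pure-Python reference step


def step(world: World, config: SimConfig, rng: np.random.Generator) -> World:
    """One time step of the full sub-step sequence, in place (reference
    implementation; the compiled kernel mirrors this arithmetic).

    Raises ``RuntimeError`` on any non-finite state component.
    """
    ia = config.effective_interaction()
    imode = ia.mode
    dt = config.dt
    t = world.step_count * dt
    n = world.n
    maze = world.maze
    tx, ty = maze.target.center
    eps = 1e-9
    gammas = (config.amoeboid.gamma, config.mesenchymal.gamma)
    sigmas = (config.amoeboid.sigma, config.mesenchymal.sigma)

    headings0 = world.heading.copy()
    pos0 = world.pos.copy()
    active0 = world.status == 0

    # 1. reorientation events: noisy heading redraw toward the target
    for i in range(n):
        if not active0[i]:
            continue
        if t >= world.next_reor[i] - eps or world.stuck[i] >= config.tau_stuck - eps:
            to_t = np.array([tx, ty]) - pos0[i]
            if np.linalg.norm(to_t) >= 1e-12:
                world.heading[i] = draw_heading(to_t, sigmas[world.mode[i]], rng)
            world.phase[i] = 0
            world.next_reor[i] = t + config.tau_reorient
            if world.stuck[i] >= config.tau_stuck - eps:
                world.stuck[i] = 0.0
        else:
            world.phase[i] = 1

    # 1b. alignment blend every step (after the noisy draw), using
    # step-start neighbor headings — simultaneous update
    if imode != "none":
        blended = {}
        for i in range(n):
            if not active0[i]:
                continue
            d = np.linalg.norm(pos0 - pos0[i], axis=1)
            nbr = active0 & (d >= ia.r_rep) & (d < ia.r_align)
            nbr[i] = False
            if nbr.any():
                w = ia.w_const if imode == "constant" \
                    else w_of_e(world.e_bar[i], ia)
                if w <= 0.0:
                    continue
                blended[i] = alignment_update(world.heading[i], headings0[nbr], w)
        for i, h in blended.items():
            world.heading[i] = h

    # 2. forces from step-start positions
    for i in range(n):
        if not active0[i]:
            continue
        fp = np.zeros(2)
        if world.phase[i] == 1:
            fp = config.energy.eta * world.e[i] * world.heading[i]
        F = fp - gammas[world.mode[i]] * world.vel[i]
        if imode != "none" and ia.k_rep > 0:
            scale = None
            if imode == "dynamic":
                scale = np.array([w_of_e(eb, ia) / ia.w0 if ia.w0 > 0 else 0.0
                                  for eb in world.e_bar])
            F = F + repulsion_force(i, pos0, ia, active0, pair_scale=scale)
        # 3. semi-implicit Euler + collision
        world.vel[i] = world.vel[i] + dt * F
        new_pos, normal = move_with_collision(maze, world.pos[i], world.vel[i], dt)
        world.pos[i] = new_pos
        spent = 0.0
        if normal is not None:
            # 4. mesenchymal proteolysis, then sliding projection (both modes)
            if world.mode[i] == MESENCHYMAL:
                ag = AgentState(id=i, mode=MESENCHYMAL, r=world.pos[i],
                                v=world.vel[i], e=world.e[i],
                                heading=world.heading[i])
                spent, psi = attempt_degradation(ag, maze, config.energy, dt)
                if psi:
                    world.ledger[_kernel.L_REMOVED] += spent / config.energy.k_w
            vn = float(world.vel[i] @ normal)
            if vn < 0.0:
                world.vel[i] = world.vel[i] - vn * normal
            world.stuck[i] += dt
        else:
            world.stuck[i] = 0.0
        # 5. depot update (positive-part mechanical power)
        mech = float(fp @ world.vel[i])
        if mech < 0.0:
            mech = 0.0
        raw = world.e[i] + dt * (config.energy.q - config.energy.c * world.e[i]
                                 - mech) - spent
        enew = max(0.0, raw)
        world.ledger[_kernel.L_INTAKE] += config.energy.q * dt
        world.ledger[_kernel.L_DISSIP] += config.energy.c * world.e[i] * dt
        world.ledger[_kernel.L_MECH] += mech * dt
        world.ledger[_kernel.L_SPENT] += spent
        world.ledger[_kernel.L_CLAMP] += enew - raw
        world.e[i] = enew
        world.e_bar[i] += dt * (enew - world.e_bar[i]) / ia.tau_w
        # 6. arrival
        if (world.pos[i, 0] - tx) ** 2 + (world.pos[i, 1] - ty) ** 2 \
                <= maze.target.radius ** 2:
            world.status[i] = 1
            world.arrival[i] = t + dt
        if not (np.all(np.isfinite(world.pos[i])) and
                np.all(np.isfinite(world.vel[i])) and np.isfinite(world.e[i])):
            raise RuntimeError(f"non-finite state for agent {i} at t={t:g}")
    world.step_count += 1
    return world


# ---------------------------------------------------------------------------
# Results


@dataclass
class SimResult:
    """Observables of one run."""

    trajectories: pd.DataFrame | None
    arrival_time: np.ndarray
    status: np.ndarray
    modes: np.ndarray
    energy_trace: pd.DataFrame
    wall_mass_removed: float
    energy_ledger: dict
    config: SimConfig
    seed: int

    def population(self, mode: str) -> int:
        code = MESENCHYMAL if mode == "mesenchymal" else AMOEBOID
        return int(np.sum(self.modes == code))

    def successes(self, mode: str) -> int:
        code = MESENCHYMAL if mode == "mesenchymal" else AMOEBOID
        return int(np.sum((self.modes == code) & (self.status == 1)))

    @property
    def success_counts(self) -> dict:
        return {name: self.successes(name) for name in ("mesenchymal", "amoeboid")}

    def to_summary_dict(self) -> dict:
        out = {"seed": self.seed, "wall_mass_removed": self.wall_mass_removed,
               "arrival_times": [None if np.isnan(a) else float(a)
                                 for a in self.arrival_time],
               "energy_ledger": self.energy_ledger,
               "config": self.config.to_dict()}
        for name in ("mesenchymal", "amoeboid"):
            pop = self.population(name)
            out[f"n_{name}"] = pop
            out[f"success_{name}"] = self.successes(name)
            out[f"success_rate_{name}"] = (self.successes(name) / pop
                                           if pop else None)
        return out


def _record_sample(rows: list, world: World, t: float):
    rows.append((t, world.pos.copy(), world.vel.copy(), world.e.copy(),
                 world.phase.copy(), world.status.copy()))


def _samples_to_frame(rows, modes) -> pd.DataFrame:
    n = len(modes)
    mode_names = np.array([MODE_NAMES[m] for m in modes])
    frames = []
    ids = np.arange(n)
    for t, pos, vel, e, phase, status in rows:
        frames.append(pd.DataFrame({
            "t": np.full(n, t), "id": ids, "mode": mode_names,
            "x": pos[:, 0], "y": pos[:, 1], "vx": vel[:, 0], "vy": vel[:, 1],
            "e": e, "phase": phase,
            "status": np.where(status == 1, "arrived", "active")}))
    return pd.concat(frames, ignore_index=True)


def run(config: SimConfig, backend: str = "numba",
        record_trajectories: bool = True) -> SimResult:
    """Integrate one realization until ``t_max`` or all agents arrive."""
    world = build_world(config)
    n_steps = config.n_steps()
    dt = config.dt
    ia = config.effective_interaction()
    rows: list = []
    _record_sample(rows, world, 0.0)

    if backend == "python":
        rng = np.random.default_rng(derive_seed(config.seed, 2))
        while world.step_count < n_steps and np.any(world.status == 0):
            step(world, config, rng)
            if world.step_count % config.sample_stride == 0:
                _record_sample(rows, world, world.step_count * dt)
    elif backend == "numba":
        _kernel.seed(derive_seed(config.seed, 2))
        m = world.maze
        stride = max(1, int(config.sample_stride))
        while world.step_count < n_steps and np.any(world.status == 0):
            chunk = min(stride, n_steps - world.step_count)
            bad = _kernel.advance(
                m.wall_mass, m.cell_size, m.world_extent[0], m.world_extent[1],
                m.target.center[0], m.target.center[1], m.target.radius,
                world.pos, world.vel, world.e, world.e_bar, world.heading,
                world.mode, world.phase, world.next_reor, world.stuck,
                world.status, world.arrival,
                world.step_count, chunk, dt, config.tau_reorient,
                config.tau_stuck,
                config.energy.eta, config.energy.q, config.energy.c,
                config.energy.k_w, config.energy.reach,
                config.energy.max_deg_mass,
                config.amoeboid.gamma, config.mesenchymal.gamma,
                config.amoeboid.sigma, config.mesenchymal.sigma,
                _IMODE_CODE[ia.mode], ia.r_rep, ia.r_align, ia.k_rep,
                ia.w_const, ia.w0,
                ia.e_half if ia.e_half is not None else 1.0, ia.n_hill,
                ia.tau_w, world.ledger)
            if bad >= 0:
                raise RuntimeError(
                    f"non-finite state for agent {bad} near t="
                    f"{world.step_count * dt:g}")
            world.step_count += chunk
            _record_sample(rows, world, world.step_count * dt)
    else:
        raise ValueError(f"unknown backend {backend!r}")

    ledger = world.ledger
    energy_ledger = {
        "intake": float(ledger[_kernel.L_INTAKE]),
        "dissipation": float(ledger[_kernel.L_DISSIP]),
        "mechanical": float(ledger[_kernel.L_MECH]),
        "proteolysis": float(ledger[_kernel.L_SPENT]),
        "clamped": float(ledger[_kernel.L_CLAMP]),
        "n_steps": world.step_count,
    }
    trace = pd.DataFrame({"t": [r[0] for r in rows],
                          "mean_e": [float(np.mean(r[3])) for r in rows]})
    traj = _samples_to_frame(rows, world.mode) if record_trajectories else None
    result = SimResult(
        trajectories=traj,
        arrival_time=world.arrival.copy(),
        status=world.status.copy(),
        modes=world.mode.copy(),
        energy_trace=trace,
        wall_mass_removed=float(ledger[_kernel.L_REMOVED]),
        energy_ledger=energy_ledger,
        config=config,
        seed=config.seed,
    )
    logger.info("run seed=%d q=%g f_mes=%g interaction=%s -> success %s",
                config.seed, config.energy.q, config.mes_fraction, ia.mode,
                result.success_counts)
    return result


# ---------------------------------------------------------------------------
# Sweeps


def sweep(base: SimConfig, mes_fractions, q_values, n_reps: int,
          seed0: int, record_trajectories: bool = False) -> pd.DataFrame:
    """Replicate ensemble over a (mes_fraction, q) grid.

    Per cell and rep, the run seed is derived from the seed root and the cell
    *values* (so identical conditions across sweeps share runs), while the
    generated-maze seed is derived from the rep index only — every cell of a
    given rep sees the same environment, making cross-cell comparisons
    paired.  Loaded (file) mazes stay fixed.  Returns a tidy summary frame
    (mode, mes_fraction, q, interaction, mean_success, se, n_reps) with the
    per-run table in ``.attrs['runs']``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    mes_fractions = list(mes_fractions)
    q_values = list(q_values)
    if not mes_fractions or not q_values:
        raise ValueError("empty sweep grid")
    imode_id = _IMODE_CODE[base.interaction.mode]
    records = []
    for f in mes_fractions:
        for q in q_values:
            for rep in range(n_reps):
                run_seed = derive_seed(seed0, int(round(f * 1000)),
                                       int(round(q * 1000)), imode_id, rep)
                cfg = replace(base, seed=run_seed, mes_fraction=f,
                              energy=replace(base.energy, q=q))
                if base.maze_file is None and base.maze is not None:
                    cfg = replace(cfg, maze=replace(
                        base.maze, seed=derive_seed(seed0, 9999, rep)))
                res = run(cfg, record_trajectories=record_trajectories)
                for mode in ("mesenchymal", "amoeboid"):
                    pop = res.population(mode)
                    if pop == 0:
                        continue
                    records.append({
                        "mode": mode, "mes_fraction": f, "q": q,
                        "interaction": base.interaction.mode, "rep": rep,
                        "seed": run_seed,
                        "success": res.successes(mode) / pop, "n_pop": pop})
    runs_df = pd.DataFrame.from_records(records)
    grouped = runs_df.groupby(["mode", "mes_fraction", "q", "interaction"],
                              as_index=False)
    summary = grouped.agg(mean_success=("success", "mean"),
                          sd=("success", "std"),
                          n_reps=("success", "size"))
    summary["se"] = summary["sd"].fillna(0.0) / np.sqrt(summary["n_reps"])
    summary = summary.drop(columns="sd")
    summary.attrs["runs"] = runs_df
    return summary
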
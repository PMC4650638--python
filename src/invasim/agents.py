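"""Single-agent state and dynamics: propulsion, drag, wall response,
proteolysis, and the internal energy depot.

Each agent carries an internal energy depot e(t) that is filled at a constant
environmental rate q and drained by maintenance (c*e), by the mechanical power
delivered to motion, and by proteolysis of maze walls.  Propulsion is the
standard depot form F_prop = theta * eta * e * e_hat, active only during the
locomotion phase (theta = 1); the heading e_hat is redrawn at reorientation
events as the direction to the target plus Gaussian angular noise, with
mode-specific spread (amoeboids noisy "path finders", mesenchymals persistent
"path generators").  Mesenchymal agents additionally degrade wall material in
front of them, but only when the depot can pay the full proteolysis cost of
the wall element — the energetic gate that produces the blocked low-energy
regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .maze import MazeGrid

__all__ = [
    "MESENCHYMAL",
    "AMOEBOID",
    "AgentState",
    "ModeParams",
    "EnergyParams",
    "init_population",
    "draw_heading",
    "propulsion_force",
    "drag_force",
    "resolve_wall_contact",
    "attempt_degradation",
    "energy_step",
    "stationary_energy",
]

AMOEBOID = 0
MESENCHYMAL = 1

MODE_NAMES = {AMOEBOID: "amoeboid", MESENCHYMAL: "mesenchymal"}

ORIENTING = 0
LOCOMOTING = 1

ACTIVE = 0
ARRIVED = 1


@dataclass
class AgentState:
    """Full state of one agent (mass m = 1 for all agents)."""

    id: int
    mode: int  # AMOEBOID or MESENCHYMAL
    r: np.ndarray  # position, world units
    v: np.ndarray  # velocity, world units / time
    e: float  # internal energy >= 0
    heading: np.ndarray  # unit vector of propulsion direction
    phase: int = LOCOMOTING  # ORIENTING (theta=0) or LOCOMOTING (theta=1)
    next_reorientation: float = 0.0
    status: int = ACTIVE

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=np.float64)
        self.v = np.asarray(self.v, dtype=np.float64)
        self.heading = np.asarray(self.heading, dtype=np.float64)


@dataclass(frozen=True)
class ModeParams:
    """Mode-specific motility constants.

    gamma : drag coefficient (gamma_M > gamma_A: mesenchymal cells adhere more
        strongly to the ECM).
    sigma : heading-noise standard deviation, radians (sigma_A > sigma_M:
        amoeboids are less directional).
    can_degrade : proteolysis capability (mesenchymal only).
    """

    gamma: float
    sigma: float
    can_degrade: bool

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class EnergyParams:
    """Depot dynamics constants.

    q : environmental energy intake rate.
    c : dissipation rate of internal energy (basic cellular maintenance).
    eta : conversion rate of internal energy into propulsion force.
    k_w : energy cost per unit wall mass degraded.
    reach : proteolysis reach ahead of the agent, world units.
    max_deg_mass : wall mass degradable per proteolysis event (default: one
        wall unit W0); together with the post-event recharge this bounds the
        degradation rate.
    """

    q: float
    c: float = 0.1
    eta: float = 0.18
    k_w: float = 5.5
    reach: float = 6.0
    max_deg_mass: float = 1.0

    def __post_init__(self):
        for name in ("q", "c", "eta", "k_w", "reach", "max_deg_mass"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def init_population(n: int, mes_fraction: float, maze: MazeGrid, e_init: float,
                    rng: np.random.Generator, *,
                    sigma_mes: float = 0.2, sigma_amo: float = 1.0,
                    tau_reorient: float = 10.0) -> list[AgentState]:
    """Place ``round(n*mes_fraction)`` mesenchymal + rest amoeboid agents
    uniformly in the start disc, at rest, with headings drawn toward the
    target under mode noise."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= mes_fraction <= 1.0:
        raise ValueError("mes_fraction must be in [0, 1]")
    n_mes = int(round(n * mes_fraction))
    cx, cy = maze.start.center
    radius = maze.start.radius
    tx, ty = maze.target.center
    agents = []
    for i in range(n):
        mode = MESENCHYMAL if i < n_mes else AMOEBOID
        while True:  # rejection-sample the disc, open cells only
            ang = rng.uniform(0.0, 2.0 * math.pi)
            rad = radius * math.sqrt(rng.uniform())
            pos = np.array([cx + rad * math.cos(ang), cy + rad * math.sin(ang)])
            if not maze.blocked(pos):
                break
        to_target = np.array([tx - pos[0], ty - pos[1]])
        to_target /= np.linalg.norm(to_target)
        sigma = sigma_mes if mode == MESENCHYMAL else sigma_amo
        heading = draw_heading(to_target, sigma, rng)
        agents.append(AgentState(id=i, mode=mode, r=pos, v=np.zeros(2),
                                 e=e_init, heading=heading,
                                 phase=LOCOMOTING,
                                 next_reorientation=tau_reorient))
    return agents


def draw_heading(target_direction, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate the unit cue direction by an angle ~ Normal(0, sigma^2)."""
    d = np.asarray(target_direction, dtype=np.float64)
    norm = np.linalg.norm(d)
    if norm == 0.0:
        raise ValueError("target_direction must be non-zero")
    d = d / norm
    ang = sigma * rng.standard_normal()
    ca, sa = math.cos(ang), math.sin(ang)
    return np.array([d[0] * ca - d[1] * sa, d[0] * sa + d[1] * ca])


def propulsion_force(e: float, heading, phase: int, eta: float) -> np.ndarray:
    """F_prop = theta * eta * e * e_hat; zero during the orientation phase."""
    if phase != LOCOMOTING:
        return np.zeros(2)
    return eta * e * np.asarray(heading, dtype=np.float64)


def drag_force(v, gamma: float) -> np.ndarray:
    """Stokes-like drag -gamma*v; gamma encodes cell-ECM adhesion strength."""
    return -gamma * np.asarray(v, dtype=np.float64)


def resolve_wall_contact(v, normal) -> np.ndarray:
    """Zero the into-wall velocity component, keep the tangential one.

    ``v' = v - min(0, v . n_hat) n_hat`` — the agent slides along the wall.
    Applied identically to both motility modes.
    """
    v = np.asarray(v, dtype=np.float64)
    n = np.asarray(normal, dtype=np.float64)
    vn = float(v @ n)
    if vn < 0.0:
        return v - vn * n
    return v.copy()


def degradation_targets(maze: MazeGrid, pos, heading, reach: float) -> list[tuple[int, int]]:
    """Wall cells whose centers lie in the disc of radius ``reach`` centered
    ``reach`` ahead of the agent, sorted nearest-to-agent first."""
    cs = maze.cell_size
    cx = pos[0] + reach * heading[0]
    cy = pos[1] + reach * heading[1]
    nx, ny = maze.shape
    ix0 = max(0, int((cx - reach) // cs))
    ix1 = min(nx - 1, int((cx + reach) // cs))
    iy0 = max(0, int((cy - reach) // cs))
    iy1 = min(ny - 1, int((cy + reach) // cs))
    cells = []
    for ix in range(ix0, ix1 + 1):
        for iy in range(iy0, iy1 + 1):
            if maze.wall_mass[ix, iy] <= 0.0:
                continue
            ccx, ccy = maze.cell_center(ix, iy)
            if (ccx - cx) ** 2 + (ccy - cy) ** 2 <= reach * reach:
                d2 = (ccx - pos[0]) ** 2 + (ccy - pos[1]) ** 2
                cells.append((d2, ix, iy))
    cells.sort()
    return [(ix, iy) for _, ix, iy in cells]


def attempt_degradation(agent: AgentState, maze: MazeGrid, params: EnergyParams,
                        dt: float) -> tuple[float, int]:
    """Proteolysis attempt by a wall-contacting mesenchymal agent.

    The agent targets the nearest wall cell within its reach disc and clears
    up to ``max_deg_mass`` of it — but only if the depot can pay the full
    proteolysis cost ``k_w * mass`` of that removal (the energy level must
    exceed the degradation energetic cost; there is no partial, on-credit
    chipping).  Returns ``(spent_energy, psi)``; ``psi = 1`` iff mass was
    removed.  Mutates the maze in place.
    """
    if agent.mode != MESENCHYMAL:
        raise ValueError("attempt_degradation called on a non-mesenchymal agent")
    targets = degradation_targets(maze, agent.r, agent.heading, params.reach)
    if not targets:
        return 0.0, 0
    ix, iy = targets[0]
    mass = min(maze.wall_mass[ix, iy], params.max_deg_mass)
    cost = params.k_w * mass
    if mass <= 0.0 or agent.e < cost:
        return 0.0, 0
    maze.wall_mass[ix, iy] -= mass
    return cost, 1


def energy_step(e: float, params: EnergyParams, mech_power: float,
                spent_degradation: float, dt: float) -> float:
    """One explicit Euler update of the depot:

    ``e' = max(0, e + dt*(q - c*e - max(0, P_mech)) - spent)``.

    The mechanical drain is the positive part of F_prop . v — the depot pays
    for propulsion work but cannot harvest energy while being pushed against
    its own heading.
    """
    if e < 0:
        raise ValueError("e must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    drain = max(0.0, mech_power)
    e2 = e + dt * (params.q - params.c * e - drain) - spent_degradation
    return max(0.0, e2)


def stationary_energy(q: float, c: float = 0.1, eta: float = 1.0,
                      gamma: float = 1.0) -> float:
    """Free-space stationary depot level for a noiseless locomoting agent.

    At stationarity the force balance gives v* = eta*e*/gamma and the energy
    balance q = c*e* + eta^2 e*^2 / gamma, whose positive root is

    ``e* = gamma * (-c + sqrt(c^2 + 4 eta^2 q / gamma)) / (2 eta^2)``.
    """
    return gamma * (-c + math.sqrt(c * c + 4.0 * eta * eta * q / gamma)) / (2.0 * eta * eta)
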
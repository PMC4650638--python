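"""Pairwise agent-agent interactions: short-range repulsion and longer-range
heading alignment with a constant or energy-gated weight.

Repulsion (linear spring in overlap, range ``r_rep``) accounts for finite cell
volume; alignment acts in the annulus ``[r_rep, r_align)`` and blends an
agent's freshly drawn heading with the mean heading of its neighbors at
weight w (crowd influence; ``1 - w`` is the agent's "self confidence").
In the dynamic mode w is a switch-like decreasing function of the agent's own
depot energy, modelling cell-cell coupling as a stress response: strong under
metabolic stress, vanishing when energy is ample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "InteractionParams",
    "repulsion_force",
    "alignment_update",
    "w_of_e",
    "pair_unit_vector",
]

INTERACTION_MODES = ("none", "constant", "dynamic")


@dataclass(frozen=True)
class InteractionParams:
    """Interaction block of the run configuration.

    mode : 'none', 'constant' (w = w_const) or 'dynamic' (w = w(e)).
    r_rep / r_align : repulsion range and maximum alignment range, world
        units; alignment acts on the annulus [r_rep, r_align).
    k_rep : repulsion spring constant.
    w_const : constant crowd weight (0.2: 20% crowd influence).
    w0, e_half, n_hill : low-energy plateau, half-weight energy and steepness
        of the switch-like dynamic weight w(e) = w0 / (1 + (e/e_half)^n).
        ``e_half = None`` resolves to the free-space amoeboid stationary
        energy at q = 0.6, the top of the stressed intake range.
    tau_w : relaxation time of the stress read-out: the dynamic weight is
        evaluated on a low-pass-filtered depot level (time constant tau_w)
        rather than the instantaneous energy, so brief dips — e.g. right
        after paying a proteolysis cost — do not flicker the switch.
    """

    mode: str = "none"
    r_rep: float = 6.0
    r_align: float = 30.0
    k_rep: float = 0.3
    w_const: float = 0.2
    w0: float = 0.2
    e_half: float | None = None
    n_hill: float = 20.0
    tau_w: float = 10.0

    def __post_init__(self):
        if self.mode not in INTERACTION_MODES:
            raise ValueError(f"mode must be one of {INTERACTION_MODES}")
        if not 0.0 < self.r_rep < self.r_align:
            raise ValueError("need 0 < r_rep < r_align")
        if not 0.0 <= self.w_const <= 1.0 or not 0.0 <= self.w0 <= 1.0:
            raise ValueError("weights must be in [0, 1]")
        if self.e_half is not None and self.e_half <= 0:
            raise ValueError("e_half must be > 0")
        if self.n_hill < 1:
            raise ValueError("n_hill must be >= 1")
        if self.tau_w <= 0:
            raise ValueError("tau_w must be > 0")


def pair_unit_vector(i: int, j: int) -> np.ndarray:
    """Deterministic pseudo-random unit vector for a coincident agent pair,
    seeded by the unordered pair indices (no RNG state consumed)."""
    a, b = (i, j) if i < j else (j, i)
    h = (a * 2654435761 ^ b * 40503) & 0xFFFFFFFF
    h = (h * 1103515245 + 12345) & 0x7FFFFFFF
    ang = 2.0 * math.pi * h / float(0x80000000)
    return np.array([math.cos(ang), math.sin(ang)])


def repulsion_force(i: int, positions: np.ndarray, params: InteractionParams,
                    active: np.ndarray | None = None,
                    pair_scale: np.ndarray | None = None) -> np.ndarray:
    """Soft-core repulsion on agent ``i`` from all active agents within
    ``r_rep``: sum of k_rep*(r_rep - d) along the center-to-center direction.

    A coincident pair (d = 0) contributes k_rep*r_rep along a deterministic
    pseudo-random direction fixed by the pair indices (sign: the smaller
    index is pushed along the vector).  ``pair_scale`` (per-agent factors in
    [0, 1], e.g. the stress response of each agent) scales each pair's
    contribution by the mean of the two factors.
    """
    positions = np.asarray(positions, dtype=np.float64)
    n = positions.shape[0]
    force = np.zeros(2)
    for j in range(n):
        if j == i or (active is not None and not active[j]):
            continue
        dvec = positions[i] - positions[j]
        d = float(np.linalg.norm(dvec))
        if d >= params.r_rep:
            continue
        if d > 1e-12:
            u = dvec / d
        else:
            u = pair_unit_vector(i, j)
            if i > j:
                u = -u
        f = params.k_rep * (params.r_rep - d)
        if pair_scale is not None:
            f *= 0.5 * (pair_scale[i] + pair_scale[j])
        force += f * u
    return force


def alignment_update(heading_i, neighbor_headings, w: float) -> np.ndarray:
    """Blend the agent's heading with the normalized mean neighbor heading:

    ``e_hat' = normalize((1 - w) e_hat_i + w * normalize(sum_j e_hat_j))``.

    With no neighbors, or on exact cancellation of the blend, the heading is
    unchanged.  The engine applies this every integration step (after the
    noisy redraw on reorientation steps), so w is a per-step crowd influence.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must be in [0, 1]")
    h = np.asarray(heading_i, dtype=np.float64)
    nbrs = np.asarray(neighbor_headings, dtype=np.float64)
    if nbrs.size == 0:
        return h.copy()
    s = nbrs.sum(axis=0)
    sn = float(np.linalg.norm(s))
    if sn == 0.0:
        return h.copy()
    blend = (1.0 - w) * h + w * (s / sn)
    bn = float(np.linalg.norm(blend))
    if bn < 1e-12:
        return h.copy()
    return blend / bn


def w_of_e(e: float, params: InteractionParams) -> float:
    """Switch-like stress-response weight w(e) = w0 / (1 + (e/e_half)^n).

    Equals w0 at e = 0, w0/2 at e = e_half, strictly decreasing, and goes to
    zero as e grows: interaction is strong only under metabolic stress.
    """
    if e < 0:
        raise ValueError("e must be >= 0")
    if params.e_half is None:
        raise ValueError("e_half unresolved; finalize the configuration first")
    return params.w0 / (1.0 + (e / params.e_half) ** params.n_hill)
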
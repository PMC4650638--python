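"""Compiled time-stepping kernel.

One numba-jitted function advances the full population over a block of steps,
mirroring the per-operation semantics of :mod:`invasim.agents`,
:mod:`invasim.interactions` and :mod:`invasim.maze` (the pure-Python
``engine.step`` is the readable reference; the two are cross-checked in the
test suite).  All randomness comes from numba's global RandomState, seeded
once per run via :func:`seed`.

Sub-step order per step (agent ids ascending, simultaneous neighbor
evaluation from step-start state):

1. reorientation events (schedule or stuck-timer): noisy heading redraw
   toward the target;
1b. alignment blend of the heading toward the mean step-start neighbor
    heading (annulus [r_rep, r_align)), applied every integration step with
    weight w;
2. forces: propulsion (locomotion phase only) + drag + pairwise repulsion;
3. semi-implicit Euler: v += dt*F, position via sub-stepped collision;
4. on wall contact: mesenchymal proteolysis attempt, then normal-velocity
   projection (both modes slide);
5. depot update with positive-part mechanical power;
6. arrival check against the target disc.
"""

import math

import numpy as np
from numba import njit

# interaction mode codes
IMODE_NONE = 0
IMODE_CONST = 1
IMODE_DYNAMIC = 2

# ledger slots
L_INTAKE = 0
L_DISSIP = 1
L_MECH = 2
L_SPENT = 3
L_CLAMP = 4
L_REMOVED = 5
N_LEDGER = 6


@njit(cache=True)
def seed(s):
    np.random.seed(s)


@njit(cache=True, inline="always")
def _blocked(wall, cs, wx, wy, px, py):
    if px < 0.0 or py < 0.0 or px >= wx or py >= wy:
        return True
    ix = int(px // cs)
    iy = int(py // cs)
    return wall[ix, iy] > 0.0


@njit(cache=True, inline="always")
def _pair_angle(i, j):
    a, b = (i, j) if i < j else (j, i)
    h = (a * 2654435761 ^ b * 40503) & 0xFFFFFFFF
    h = (h * 1103515245 + 12345) & 0x7FFFFFFF
    return 2.0 * math.pi * h / 2147483648.0


@njit(cache=True)
def advance(wall, cs, wx, wy, tx, ty, t_radius,
            pos, vel, e, e_bar, heading, mode, phase, next_reor, stuck, status,
            arrival,
            step0, n_steps, dt, tau_reor, tau_stuck,
            eta, q, c, k_w, reach, max_deg_mass,
            gamma_a, gamma_m, sigma_a, sigma_m,
            imode, r_rep, r_align, k_rep, w_const, w0, e_half, n_hill, tau_w,
            ledger):
    """Advance ``n_steps`` steps in place.  Returns -1 on success, else the
    id of the first agent whose state went non-finite."""
    n = pos.shape[0]
    Fx = np.zeros(n)
    Fy = np.zeros(n)
    asx = np.zeros(n)  # alignment neighbor-heading sums
    asy = np.zeros(n)
    acnt = np.zeros(n, dtype=np.int64)
    stress = np.ones(n)  # per-agent stress factor w(e_bar)/w0 (dynamic mode)
    reor = np.zeros(n, dtype=np.uint8)
    eps = 1e-9

    for s in range(n_steps):
        t = (step0 + s) * dt

        any_active = False
        for i in range(n):
            if status[i] == 0:
                any_active = True
                break
        if not any_active:
            return -1

        # ---- pair sweep from step-start state: repulsion forces (d < r_rep)
        # and alignment heading sums (r_rep <= d < r_align) ----
        for i in range(n):
            Fx[i] = 0.0
            Fy[i] = 0.0
            asx[i] = 0.0
            asy[i] = 0.0
            acnt[i] = 0
        if imode == IMODE_DYNAMIC:
            for i in range(n):
                stress[i] = 1.0 / (1.0 + (e_bar[i] / e_half) ** n_hill)
        if imode != IMODE_NONE:
            for i in range(n - 1):
                if status[i] != 0:
                    continue
                for j in range(i + 1, n):
                    if status[j] != 0:
                        continue
                    dx = pos[i, 0] - pos[j, 0]
                    dy = pos[i, 1] - pos[j, 1]
                    d2 = dx * dx + dy * dy
                    if d2 >= r_align * r_align:
                        continue
                    d = math.sqrt(d2)
                    if d >= r_rep:
                        asx[i] += heading[j, 0]
                        asy[i] += heading[j, 1]
                        acnt[i] += 1
                        asx[j] += heading[i, 0]
                        asy[j] += heading[i, 1]
                        acnt[j] += 1
                    elif k_rep > 0.0:
                        if d > 1e-12:
                            ux = dx / d
                            uy = dy / d
                        else:
                            ang = _pair_angle(i, j)
                            ux = math.cos(ang)
                            uy = math.sin(ang)
                        f = k_rep * (r_rep - d)
                        if imode == IMODE_DYNAMIC:
                            # stress-induced coupling: contact interaction
                            # engages only for metabolically stressed pairs
                            f *= 0.5 * (stress[i] + stress[j])
                        Fx[i] += f * ux
                        Fy[i] += f * uy
                        Fx[j] -= f * ux
                        Fy[j] -= f * uy

        # ---- 1. reorientation events: noisy heading redraw toward target ----
        for i in range(n):
            reor[i] = 0
            if status[i] != 0:
                continue
            if t >= next_reor[i] - eps or stuck[i] >= tau_stuck - eps:
                reor[i] = 1
                dxt = tx - pos[i, 0]
                dyt = ty - pos[i, 1]
                dn = math.sqrt(dxt * dxt + dyt * dyt)
                if dn >= 1e-12:
                    sig = sigma_m if mode[i] == 1 else sigma_a
                    ang = sig * np.random.standard_normal()
                    ca = math.cos(ang)
                    sa = math.sin(ang)
                    bx = dxt / dn
                    by = dyt / dn
                    heading[i, 0] = bx * ca - by * sa
                    heading[i, 1] = bx * sa + by * ca
                phase[i] = 0
                next_reor[i] = t + tau_reor
                if stuck[i] >= tau_stuck - eps:
                    stuck[i] = 0.0
            else:
                phase[i] = 1

        # ---- alignment blend (every step, after the noisy draw) ----
        if imode != IMODE_NONE:
            for i in range(n):
                if status[i] != 0 or acnt[i] == 0:
                    continue
                sn = math.sqrt(asx[i] * asx[i] + asy[i] * asy[i])
                if sn == 0.0:
                    continue
                if imode == IMODE_CONST:
                    w = w_const
                else:  # stress switch reads the low-pass-filtered depot
                    w = w0 * stress[i]
                if w <= 0.0:
                    continue
                bx2 = (1.0 - w) * heading[i, 0] + w * asx[i] / sn
                by2 = (1.0 - w) * heading[i, 1] + w * asy[i] / sn
                bn = math.sqrt(bx2 * bx2 + by2 * by2)
                if bn > 1e-12:
                    heading[i, 0] = bx2 / bn
                    heading[i, 1] = by2 / bn

        # ---- 3-6. per-agent integration ----
        for i in range(n):
            if status[i] != 0:
                continue
            ga = gamma_m if mode[i] == 1 else gamma_a
            fpx = 0.0
            fpy = 0.0
            if phase[i] == 1:
                fpx = eta * e[i] * heading[i, 0]
                fpy = eta * e[i] * heading[i, 1]
            fx = fpx - ga * vel[i, 0] + Fx[i]
            fy = fpy - ga * vel[i, 1] + Fy[i]
            vel[i, 0] += dt * fx
            vel[i, 1] += dt * fy

            # collision-aware move (sub-steps <= cs/4, bisection to cs/100)
            dispx = vel[i, 0] * dt
            dispy = vel[i, 1] * dt
            length = math.sqrt(dispx * dispx + dispy * dispy)
            contact = False
            nxv = 0.0
            nyv = 0.0
            if length > 0.0:
                nsub = int(math.ceil(length / (cs / 4.0)))
                if nsub < 1:
                    nsub = 1
                segx = dispx / nsub
                segy = dispy / nsub
                seg_len = length / nsub
                px = pos[i, 0]
                py = pos[i, 1]
                tol = cs / 100.0
                for _k in range(nsub):
                    cx = px + segx
                    cy = py + segy
                    if _blocked(wall, cs, wx, wy, cx, cy):
                        lo = 0.0
                        hi = 1.0
                        while (hi - lo) * seg_len > tol:
                            mid = 0.5 * (lo + hi)
                            if _blocked(wall, cs, wx, wy, px + mid * segx,
                                        py + mid * segy):
                                hi = mid
                            else:
                                lo = mid
                        contact = True
                        ccx = px + hi * segx
                        ccy = py + hi * segy
                        px = px + lo * segx
                        py = py + lo * segy
                        # outward normal: occupancy gradient on 3x3 stencil
                        cix = int(math.floor(ccx / cs))
                        ciy = int(math.floor(ccy / cs))
                        gx = 0.0
                        gy = 0.0
                        nx_cells = wall.shape[0]
                        ny_cells = wall.shape[1]
                        for ddx in range(-1, 2):
                            for ddy in range(-1, 2):
                                if ddx == 0 and ddy == 0:
                                    continue
                                jx = cix + ddx
                                jy = ciy + ddy
                                occ = 1.0
                                if 0 <= jx < nx_cells and 0 <= jy < ny_cells:
                                    occ = 1.0 if wall[jx, jy] > 0.0 else 0.0
                                if occ > 0.0:
                                    gx += ddx
                                    gy += ddy
                        gn = math.sqrt(gx * gx + gy * gy)
                        if gn > 0.0:
                            nxv = -gx / gn
                            nyv = -gy / gn
                        else:  # degenerate stencil: oppose the motion
                            nxv = -segx / seg_len
                            nyv = -segy / seg_len
                        break
                    px = cx
                    py = cy
                pos[i, 0] = px
                pos[i, 1] = py

            # ---- 4. wall contact: proteolysis then sliding projection ----
            spent = 0.0
            if contact:
                if mode[i] == 1:  # mesenchymal proteolysis attempt
                    dcx = pos[i, 0] + reach * heading[i, 0]
                    dcy = pos[i, 1] + reach * heading[i, 1]
                    nx_cells = wall.shape[0]
                    ny_cells = wall.shape[1]
                    ix0 = int((dcx - reach) // cs)
                    ix1 = int((dcx + reach) // cs)
                    iy0 = int((dcy - reach) // cs)
                    iy1 = int((dcy + reach) // cs)
                    if ix0 < 0:
                        ix0 = 0
                    if iy0 < 0:
                        iy0 = 0
                    if ix1 > nx_cells - 1:
                        ix1 = nx_cells - 1
                    if iy1 > ny_cells - 1:
                        iy1 = ny_cells - 1
                    best_d2 = 1e300
                    bix = -1
                    biy = -1
                    for jx in range(ix0, ix1 + 1):
                        for jy in range(iy0, iy1 + 1):
                            if wall[jx, jy] <= 0.0:
                                continue
                            ccx2 = (jx + 0.5) * cs
                            ccy2 = (jy + 0.5) * cs
                            dx2 = ccx2 - dcx
                            dy2 = ccy2 - dcy
                            if dx2 * dx2 + dy2 * dy2 <= reach * reach:
                                ax = ccx2 - pos[i, 0]
                                ay = ccy2 - pos[i, 1]
                                d2 = ax * ax + ay * ay
                                if d2 < best_d2:
                                    best_d2 = d2
                                    bix = jx
                                    biy = jy
                    if bix >= 0:
                        m_rm = wall[bix, biy]
                        if m_rm > max_deg_mass:
                            m_rm = max_deg_mass
                        cost = k_w * m_rm
                        if m_rm > 0.0 and e[i] >= cost:
                            wall[bix, biy] -= m_rm
                            spent = cost
                            ledger[L_REMOVED] += m_rm
                # sliding: remove the into-wall velocity component
                vn = vel[i, 0] * nxv + vel[i, 1] * nyv
                if vn < 0.0:
                    vel[i, 0] -= vn * nxv
                    vel[i, 1] -= vn * nyv
                stuck[i] += dt
            else:
                stuck[i] = 0.0

            # ---- 5. depot update ----
            mech = fpx * vel[i, 0] + fpy * vel[i, 1]
            if mech < 0.0:
                mech = 0.0
            raw = e[i] + dt * (q - c * e[i] - mech) - spent
            enew = raw if raw > 0.0 else 0.0
            ledger[L_INTAKE] += q * dt
            ledger[L_DISSIP] += c * e[i] * dt
            ledger[L_MECH] += mech * dt
            ledger[L_SPENT] += spent
            ledger[L_CLAMP] += enew - raw
            e[i] = enew
            e_bar[i] += dt * (enew - e_bar[i]) / tau_w

            # ---- 6. arrival ----
            ddx = pos[i, 0] - tx
            ddy = pos[i, 1] - ty
            if ddx * ddx + ddy * ddy <= t_radius * t_radius:
                status[i] = 1
                arrival[i] = t + dt

            if not (math.isfinite(pos[i, 0]) and math.isfinite(pos[i, 1])
                    and math.isfinite(vel[i, 0]) and math.isfinite(vel[i, 1])
                    and math.isfinite(e[i])):
                return i
    return -1
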
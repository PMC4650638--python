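# invasim

Agent-based simulation of mixed **mesenchymal/amoeboid** tumor-cell
populations invading a maze-like extracellular matrix (ECM).

Metastasizing cells cross dense, obstacle-filled tissue toward blood
vessels using two canonical motility strategies: the *path-generating*
mesenchymal mode (directed, strongly adherent, able to open paths by
proteolytic degradation of the matrix) and the *path-finding* amoeboid
mode (fast, weakly adherent, noisy, squeezing through existing gaps but
unable to cut new ones). `invasim` lets you ask population-level
questions about this heterogeneity: when does a minority of path
generators boost everyone's invasion? when does cell-cell alignment help
or hurt? and how does metabolic stress reshape collective migration?

## Model in brief

Each of N = 50 agents carries position r, velocity v, heading ê and an
internal energy depot e, with (m = 1):

    dv/dt = θ η e ê − γ_mode v + F_rep
    de/dt = q − c e − max(0, F_prop·v) − k_w (wall mass degraded)/dt

The heading is redrawn every τ time units toward the target plus Gaussian
noise (σ_A > σ_M); walls zero the normal velocity component (sliding), and
a wall-contacting mesenchymal clears the nearest wall cell iff its depot
can pay the full proteolysis cost k_w·W0. Optional interactions add
short-range repulsion and Vicsek-style heading alignment with weight w —
constant (w = 0.2) or an energy-gated stress response
w(e) = w0 / (1 + (e/e_half)^n). The environment is a procedurally
generated labyrinth of thin, rounded walls with openings on an 800×800
arena. Success rate = fraction of a mode's agents reaching the target disc
before t_max. See `docs/methods.md` for the full model, the calibration
and its rationale.

## Worked example

```python
from invasim.engine import SimConfig, run
from invasim.agents import EnergyParams
from invasim.analysis import success_rate

for q in (0.5, 1.0):
    res = run(SimConfig(seed=1, mes_fraction=0.5, energy=EnergyParams(q=q)))
    print(f"q={q}: mesenchymal {success_rate(res, 'mesenchymal'):.2f}, "
          f"amoeboid {success_rate(res, 'amoeboid'):.2f}, "
          f"wall mass removed {res.wall_mass_removed:.0f}")
```

prints

```
q=0.5: mesenchymal 0.00, amoeboid 0.00, wall mass removed 0
q=1.0: mesenchymal 0.92, amoeboid 0.76, wall mass removed 135
```

Under metabolic stress (q = 0.5) the proteolysis cost exceeds the highest
depot level an agent can reach, so mesenchymals never degrade a wall (the
removed mass is exactly 0) and their low heading noise leaves them trapped
— the blocked regime. At ample intake (q = 1.0) mesenchymals cut 135 wall
units of new paths and nearly all of them cross, and amoeboids profit from
the same tunnels. Success rates vary considerably between random labyrinths;
ensemble statistics come from `sweep` or `scripts/acceptance.py`.

The same experiments from the shell:

```bash
invasim --out-dir out generate-maze --seed 3          # maze.txt + maze.pgm
invasim --out-dir out run config.json --name demo     # result JSON + trajectory CSV
invasim --out-dir out sweep config.json --seed 9 --n-reps 20
invasim --out-dir out clusters out/demo_trajectories.csv
```

`config.json` mirrors `SimConfig` field names, e.g.
`{"seed": 7, "mes_fraction": 0.5, "energy": {"q": 1.0}}`.

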
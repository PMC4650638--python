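# Model and methods

`invasim` simulates a fixed population of self-propelled agents — coarse-
grained tumor cells — crossing a 2D maze-like extracellular-matrix (ECM)
environment toward a target zone under a noisy directional cue. Agents come
in two permanent motility modes: *mesenchymal* ("path generating": low
heading noise, high ECM adhesion, able to degrade walls by proteolysis) and
*amoeboid* ("path finding": high heading noise, low adhesion, unable to
degrade). The central observable is the per-mode success rate: the fraction
of a mode's agents that reach the target disc before the time horizon.

## Equations of motion

Each agent (mass m = 1) obeys

    dv/dt = F_prop + F_drag + F_rep
    F_prop = theta * eta * e * e_hat        (theta = 0 while re-orienting)
    F_drag = -gamma_mode * v

with position advanced by collision-aware integration (below). The heading
e_hat is redrawn at every reorientation event (every `tau_reorient` time
units, and additionally after `tau_stuck` of continuous wall contact) as the
unit vector toward the target rotated by an angle ~ Normal(0, sigma_mode^2).
The cue is a fixed "chemoattractant" direction, deliberately unaware of the
walls.

The internal energy depot evolves as

    de/dt = q - c*e - max(0, F_prop . v) - (proteolysis spending)/dt,

clamped at zero. `q` is the environmental intake rate (the stress axis of
the study), `c*e` is maintenance dissipation, and the third term is the
mechanical power actually delivered to motion. The positive part is taken
because the depot pays for propulsion work but cannot harvest energy while
the agent is pushed against its own heading; this also makes `q/c` a hard
ceiling for the depot, which the blocked regime below relies on.

A free-space, noiseless, locomoting agent relaxes to the stationary state

    eta * e* = gamma * v*,   q = c*e* + eta^2 e*^2 / gamma
    e* = gamma * (-c + sqrt(c^2 + 4 eta^2 q / gamma)) / (2 eta^2),

which the test suite checks against simulation to 1%.

## Walls, sliding, proteolysis

The arena (800 x 800 world units) is a raster of 4-unit cells carrying wall
mass (0 = open, W0 = 1 initially). Motion is integrated semi-implicitly:
velocity update, then a straight move sub-stepped at <= cell/4 with bisection
refinement (to cell/100) that stops at the first wall contact; the domain
boundary is impenetrable, non-degradable wall. On contact the into-wall
velocity component is zeroed and the tangential one kept — both modes slide
along walls. The outward wall normal is estimated from the occupancy
gradient on the 3x3 cell neighborhood of the contact cell.

A wall-contacting mesenchymal agent attempts proteolysis: it targets the
nearest wall cell within a reach disc (radius `reach` = 6, centered `reach`
ahead of it) and clears up to `max_deg_mass` = W0 of it in one event — but
only if its depot can pay the full cost `k_w * mass` of that removal. There
is no partial, on-credit chipping: the energy level must exceed the
degradation energetic cost before any mass is removed. Cleared cells are
permanent open paths that any later agent can use; this is the only channel
of indirect (mechanistic) cooperation in the model.

Why an event gate rather than a continuous degradation rate: a rate rule
without a threshold lets any agent chip walls at rate ~ q/k_w, which varies
only linearly in q — the success curves then cannot reproduce both a fully
blocked low-intake regime and an open high-intake regime. With the event
gate the regimes separate sharply through the depot ceiling:

* q = 0.5: ceiling q/c = 5.0 < k_w*W0 = 5.5 — degradation is impossible, ever
  (mesenchymal success is exactly zero; low sigma also keeps them from
  navigating around barriers).
* q = 0.6: ceiling 6.0 — an agent must park at a wall (v ~ 0) and recharge
  past 5.5 before each event; progress is very slow.
* q = 0.8: the moving-state energy (~5.3) sits just below the gate; brief
  slow-downs trigger occasional events.
* q = 1.0: the moving-state energy (~6.0) exceeds the gate — agents chew
  through walls in stride.

## Interactions

With interactions enabled, agents within `r_rep` = 6 units repel via a
linear overlap spring (k_rep = 0.3) — a weak excluded-volume correction — and agents in the
annulus [r_rep, r_align = 30) align: each integration step the heading is
blended with the normalized mean neighbor heading,

    e_hat' = normalize((1 - w) e_hat + w * normalize(sum_j e_hat_j)),

with crowd weight w. Alignment is applied per integration step (the weight
is defined together with the integration time step), not only at
reorientation events; per-step application is what makes the crowd's
noise-averaging strong enough to visibly impair amoeboid exploration.
`w_const` = 0.2 gives the crowd 20% influence per update. In the *dynamic*
mode the weight is a switch-like stress response of the agent's own depot,

    w(e) = w0 / (1 + (e / e_half)^n),

with w0 = 0.2, n = 20 and e_half defaulting to the free-space amoeboid
stationary energy at q = 0.6 (the top of the stressed intake range). The
switch must be sharp because the amoeboid operating energies across the
studied intake ladder span a narrow range (roughly 2.5 to 3.9); a gentle
Hill exponent leaves a residual per-step weight at high intake that
measurably perturbs the dynamics, while n = 20 cleanly separates "stressed"
(w near w0) from "ample" (w near 0).

In the dynamic mode the stress response gates the *whole* coupling, not
just the heading blend: each pair's repulsion is scaled by the mean of the
two agents' stress factors w(e)/w0. This follows the interpretation of
cluster formation as stress-induced cell-cell adhesion — the contact
coupling itself is part of the induced program — and it is what lets the
dynamic mode reproduce the no-interaction behavior when depots are full
(an always-on repulsion measurably perturbs traffic through narrow
proteolysed passages even at small k_rep).

The switch reads a low-pass-filtered depot level (first-order filter with
time constant `tau_w` = 10, the depot's own relaxation time 1/c) rather
than the instantaneous energy. A cell's stress-response program — adhesion
and coupling remodelling — tracks its sustained metabolic state, not
millisecond power fluctuations; computationally, an instantaneous read-out
would flicker the switch on during every post-proteolysis recharge (the
depot drops by k_w*W0 at each degradation event), re-activating alignment
for well-fed path-generating agents and spoiling the recovery of the
no-interaction behavior at high intake.

## Maze generation

The generator produces labyrinths of thin, winding, rounded walls with
openings — blocking obstacles combined with open paths — rather than solid
blobs: walls are bands along the median level-set of a correlated Gaussian
field (correlation length `pore_scale` = 100), with the band width tuned by
bisection to a target wall-cell fraction (0.25), interrupted by openings
where an independent second field (correlation length `gap_scale` = 50)
exceeds its top `gap_fraction` = 0.25 quantile, then morphologically closed
and smoothed. Start and target discs (radius 25, near opposite corners) are
carved open. Generation is bit-reproducible given the seed. Thin walls make
single proteolysis events open passages (so the intake ladder grades
success), while gaps guarantee amoeboids navigable, winding routes.

## Calibration and default study conditions

The physical constants are a documented calibration rather than a published
table. Fixed by construction: m = 1, gamma_A = 1 < gamma_M = 2 (adhesion),
sigma_M = 0.2 < sigma_A = 1.0 rad (directionality), c = 0.1, W0 = 1,
dt = 0.05; agents start at their mode's free-space stationary depot level
(they are adapted to the medium before the assay — a cold start at a fixed
low e_init would put the whole cohort into the stressed-coupling regime
for the first tens of time units and bias the interaction comparisons).
The remaining constants were set by the following
procedure, in this order:

1. `k_w` = 5.5 places the degradation gate strictly between the depot
   ceilings at q = 0.5 (5.0) and q = 0.6 (6.0) — the blocked regime is then
   an exact energetic impossibility, not a statistical accident.
2. `eta` = 0.18 places the mesenchymal *moving-state* energy just below the
   gate at q = 0.8 and just above it at q = 1.0, so the ladder
   q in {0.5, 0.6, 0.8, 1.0} spans blocked / parked / marginal / in-stride
   degradation; it also gives free-space speeds (~0.5-0.7 units/time) that
   cross the arena in roughly a third of the horizon.
3. `k_rep` = 0.3 keeps the net effect of repulsion on success rates below
   sampling noise, as required for the energy-gated interaction to recover
   the no-interaction results when depots are full (alignment, not
   repulsion, carries the interaction phenomenology).
4. Maze geometry (above) and `tau_reorient` = 10 were chosen so amoeboids
   are motile: exploration legs of ~5-7 units against ~50-unit corridors,
   with measurable amoeboid success at q >= 0.8 and near-zero at q = 0.5.
5. Horizon `t_max` = 5000 (the cue-straight free-space crossing takes about
   a third of it); success rates are meaningfully between 0 and 1 across
   the ladder.

Default ensembles use 50 agents and 20 replicates per condition. Replicate
seeds derive from a root seed and the condition values, and the generated
maze seed depends only on the replicate index, so different conditions of a
comparison see identical environments (paired comparisons).

## Observables

* **Success rate** per mode: arrivals / mode population (absent for an empty
  mode, not zero).
* **Clusters**: single-linkage hierarchical clustering of active-agent
  positions with the dendrogram cut at radius 30 (links strictly below the
  cutoff merge); reported as the mean size of multi-agent groups and the
  number of singletons, against the realized (time- and agent-averaged)
  mean energy. Snapshots are taken at 20 evenly spaced times in the middle
  half of the run, excluding arrived agents.

## Numerical and implementation notes

* Semi-implicit Euler at dt = 0.05 (c*dt and gamma*dt well below stability
  limits); simultaneous neighbor evaluation from step-start state, so
  results are independent of agent ordering.
* The production integrator is a numba kernel; a pure-Python reference
  implementation of the identical step (`engine.step`) is kept and the two
  are cross-checked to 1e-9 over a thousand interacting, degrading steps in
  a deterministic (noise-free) configuration.
* Energy bookkeeping (intake, dissipation, mechanical work, proteolysis,
  clamping) is accumulated every step; the global identity holds to 1e-6
  per step in the tests.
* Coincident agent pairs receive a deterministic, pair-indexed repulsion
  direction so no RNG state is consumed by degenerate geometry.
* All randomness (maze field, initial placement, heading noise) descends
  from the single run seed; reruns are bit-identical.

## What the synthetic environments do and do not capture

The generated labyrinths reproduce the statistical character of a maze-like
ECM — pore scale, thin curved barriers, dead ends, openable walls — but not
any particular published geometry; absolute success rates therefore depend
on the generator settings, and only the qualitative structure (regime
ordering in q, fraction dependence, interaction effects, clustering trend)
is meaningful. Real ECM features fiber-level mechanics, strain stiffening,
and chemokine fields shaped by the matrix, none of which are modelled; the
cue here passes through walls by design. Cell shape, proliferation, death,
and mode switching are out of scope (mode assignments are permanent).

## Known limitations

* The rescue of stressed mesenchymals by constant alignment interaction
  is only marginal under this calibration (an absolute success shift of
  order 0.005, pooled over the stressed, mesenchymal-dominated region): at
  q = 0.5 any rescue is energetically impossible by the same hard gate
  that makes the blocked regime exact, and at q = 0.6 crowding partly
  hinders the park-recharge-chew cycle (neighbors jostle parked agents,
  keeping their mechanical drain positive). The interference with amoeboid
  path finding, the indirect-cooperation fraction dependence, the
  energy-gated recovery and the clustering trend are all robust; the
  rescue is the weakest reproduced effect.
* With strong alignment, dense packs can locally slow each other near
  narrow passages (single-file tunnels), an artifact of point agents with a
  repulsion range wider than a one-cell tunnel.
* The wall normal is estimated from a 3x3 stencil and is unreliable exactly
  at one-cell spikes (where the occupancy gradient cancels); the integrator
  falls back to opposing the motion direction there.
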
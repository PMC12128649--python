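# Methods

## The model

`motorclutch` simulates an ensemble of molecular clutches — integrin/adaptor
complexes that reversibly link the myosin-driven F-actin retrograde flow to a
compliant substrate — and extends the classical motor-clutch anchorage with an
orthogonal elastic spring that stores **residual strain**: pre-strain the
extracellular matrix carries before any clutch engages. The readout of
mechanosensing is the *optimal clutch number* `n_c*`, the clutch count that
minimizes the mean retrograde flow (equivalently, maximizes the traction the
ensemble transmits).

All quantities are in pN, nm, s; there is no unit-conversion layer.

### Forces

* Clutch force: Hookean, `F_c,i = k_c (x_c,i − x_s)`, positive when the actin
  flow has carried the bound clutch ahead of the substrate attachment point.
* Bond rupture: slip-bond (Bell) kinetics, `k_off* = k_off exp(F_c / F_b)`.
  The exponent is capped at 50 (a rate of ~5·10²⁰ /s fires within float
  resolution anyway) so extreme loads can never produce non-finite rates.
  By default the *signed* force is used — a compressed clutch unbinds more
  slowly; `bell_absolute_force=True` switches to `|F_c|`.
* Anchorage: a horizontal substrate spring `k_s` in parallel with an
  orthogonal spring `k_s_eps0` (set equal to `k_s` by default) of rest length
  `l`. At horizontal displacement `x_s` the restoring force is

  `F_s = k_s_eps0 (sqrt(l'² + x_s²) − l) x_s / sqrt(l'² + x_s²) + k_s x_s`

  where `l'` is the orthogonal spring's deformed length. The canonical
  variant drops the first term.
* Residual strain `eps0 = (l' − l)/l` can be stored two ways:
  * **axial** — the orthogonal spring is pre-stretched along its own axis:
    `l' = l (1 + eps0)`. The pre-stretch force is taken up by the support
    constraints, so it enters the balance only through `l'`; at small `x_s`
    the anchorage stiffens by the factor `1 + (k_s_eps0/k_s)·eps0/(1+eps0)`,
    which saturates at 2 (for equal springs) as `eps0 → ∞`. This is the
    origin of the saturation of strain sensing on stiff substrates.
  * **transverse** — the pin joining the springs is offset sideways by
    `x0 = l sqrt(eps0 (eps0 + 2))` (the exact inversion of
    `eps0 = sqrt(l² + x0²)/l − 1`), storing the residual force
    `F0 = k_s_eps0 eps0 l + k_s x0` which enters the balance additively:
    `F0 + Σ F_c,i = F_s(x_s)`. The force-law geometry keeps `l' = l`; the
    rotation of the spring is captured entirely by `F0`. With no clutches
    engaged the balance `F0 = F_s(x_s)` has a positive root, so under
    transverse strain the substrate rests at a pre-displaced baseline
    `x_s* > 0` where the local anchorage stiffness is higher — the stronger
    stiffening of the transverse mode.
* Motors: Hill force–velocity relation `v_f = v_u (1 − F/(n_m F_m))`, with
  the motor count tied to the clutch count (`n_m = n_c`). `F` is the load
  the motor ensemble actually works against: the summed engaged-clutch force
  `Σ F_c,i`. In the none/axial modes this equals `F_s` identically; in the
  transverse mode it equals `F_s − F0`, since the stored residual force is
  reacted by the constraints, not by the actin — using the raw `F_s` there
  would stall the motors through a spring they are not connected to. `v_f`
  is clamped to `[0, v_u]`: pulling motors neither reverse under super-stall
  load nor exceed their unloaded velocity.

### Equilibrium

After every event the substrate position solves
`F0 + Σ k_c (x_c,i − x_s) = F_s(x_s)`. The residual is strictly increasing
in `x_s` with slope at least `k_s + m k_c`, so the root is unique. It is
found by geometric bracket expansion followed by Newton iteration with a
bisection safeguard (absolute tolerance 1e−10 nm); the canonical variant
uses the closed form `x_s = k_c Σ x_c,i / (k_s + m k_c)`. Solver failure
raises with the offending configuration attached; it is never silently
swallowed.

## Stochastic engine

The master equation for per-clutch engagement is realized by a
first-reaction scheme: every iteration draws `t_i = −ln(u_i)/k_i` for all
clutches (`k_on` if unbound, the Bell off-rate at the current force if
bound), executes the earliest event, and advances time by it. Between
events, bound clutches advect with the flow (`x_c += v_f Δt`, with `v_f`
from the start of the interval) and unbound clutches ride with the
substrate. Consequently a clutch that binds attaches **at zero extension at
the event-time substrate position**: the balance is solved first (a
zero-force bond leaves it unchanged) and the new bond is pinned at the
root. Pinning at the interval-start position instead would give every new
bond a spurious compression of order `k_c v_f Δt` — a few pN on soft
substrates — which measurably suppresses engagement; a fine-time-step
discretization of the master equation (rates refreshed every 2 ms) was used
as an independent check that the event engine reproduces the correct means.

A *failure* is the event at which the engaged count returns to zero; the
substrate then rests again at its baseline (0, or `x_s*` under transverse
strain) and the accumulated engaged-position sum is reset to shed float
round-off. Rates are frozen between events (the force growth over one
waiting time is ≪ F_b in all regimes simulated here). Runs are driven by a
single PCG64 generator; identical (parameters, event count, seed) reproduce
traces bit for bit.

### Averaging

Summaries are time-weighted means (each post-event value weighted by the
waiting time to the next event) over the trace after a burn-in. The default
burn-in discards everything before the first global failure, removing the
deterministic initial loading ramp; a fixed-fraction burn-in is available.
Whether the original averages were time- or event-weighted is not specified
anywhere we could find; time weighting is the physically meaningful choice
for a piecewise-constant signal and is the default. Cycle time is the mean
spacing of failure times in the averaged window and is reported as missing
(not zero) when fewer than two failures occurred. "Traction force" is the
clutch-transmitted load `Σ F_c` (= `F_s` outside transverse mode);
"clutch force" is that load divided by the engaged count.

## Sweeps and optima

Mean retrograde flow is biphasic in `n_c`: small ensembles slip
frictionally (flow near `v_u`), very large ensembles drag the substrate with
little relative slip (per-clutch loading rate ~ `v_f k_s/m` → low forces →
flow back near `v_u`), and the load-and-fail regime between them minimizes
the flow. The optimum is located by a cubic interpolating spline of mean
flow against `log n_c` over a log-spaced integer grid (the grid's natural
abscissa), evaluated densely (10⁴ points) with a final three-point parabolic
refinement. Monotone curves yield a boundary optimum and are flagged.
Ties break toward the smaller clutch count. Grid construction rounds a
geometric progression to integers and deduplicates collisions with a
warning.

Each grid point averages replicate seeds (default 3) before splining; a run
that errors is excluded with a logged warning, never silently averaged.
Strain-response curves normalize the per-strain optima by the zero-strain
optimum and report rates of change as secant slopes between consecutive
normalized points.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `F_m` | 2 pN | single-motor stall force |
| `v_u` | 120 nm/s | unloaded motor velocity |
| `F_b` | 2 pN | characteristic bond rupture force |
| `k_on` | 0.3 /s | clutch engagement rate |
| `k_off` | 0.1 /s | unloaded off-rate |
| `k_c` | 0.8 pN/nm | clutch spring constant |
| `k_s` | — (required) | substrate spring constant |
| `k_s_eps0` | `k_s` | orthogonal spring constant |
| `l` | 1000 nm | orthogonal-spring rest length |

The `paper-full` preset pairs these with the full event budget (100k events,
single seed); the `desk` preset uses 20k events and three replicate seeds,
which resolves the optima to roughly ±10–20% in minutes. The reference
clutch-count grids are 25 log-spaced values in [10, 200] for
`k_s = 0.1 pN/nm` and 20 in [10, 1000] for `k_s = 1 pN/nm`.

## Problem sizes used in the shipped checks

The test suite and the acceptance script use the desk protocol for the
soft-substrate optimum and its strain response, the desk protocol for the
stiff-substrate zero-strain optimum, and the full 100k-event budget (three
replicate seeds) for the stiff-substrate strain-stiffening rates, which are
differences of two noisy optima and benefit most from the longer traces.
The threshold-effect check (strain 0.1 on the soft substrate) uses six
replicate seeds, since the expected shift (~1 clutch) is at the resolution
limit of the spline optimum. Reduced-budget assertions on stochastic optima
use the relative band 0.58–1.46 of the reference value (the band the
soft-substrate stiffening check defines); bare optima use ±20%.

## What the simulations do and do not show

The generator *is* the study system: all inputs are parameter sets, so
passing tests show internal consistency of the model and reproduction of
its published behaviour, not anything about real adhesions. Known
limitations, inherited from the model itself: one spatial dimension (no
clutch rotation or vertical force components), linear springs, no
catch-bond or tension-dependent adhesion reinforcement, no viscoelasticity
or ligand mobility, and motor count rigidly tied to clutch count. The
transverse mode represents the rotated-spring geometry only through the
additive residual force `F0`; any tilt of the clutch line of action is not
modelled. Optima on flat flow curves (the stiff substrate at high strain)
carry replicate-to-replicate jitter of order 10%, and the transverse
optimum at strain 1 approaches the upper end of the reference grid, where
single-seed estimates can hit the boundary.
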
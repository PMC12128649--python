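# motorclutch

Stochastic motor-clutch simulator for cell mechanosensing of substrate
stiffness **and stored elastic strain energy**.

Molecular clutches (integrin–adaptor complexes) reversibly couple the
myosin-driven F-actin retrograde flow to a compliant substrate. Engaged
clutches load like Hookean springs (`F_c = k_c (x_c − x_s)`), rupture with
slip-bond kinetics (`k_off* = k_off e^{F_c/F_b}`), and the motor ensemble
slows according to Hill's relation `v_f = v_u (1 − F/(n_m F_m))`. The number
of clutches `n_c` that minimizes the mean retrograde flow — the *optimal
clutch number* `n_c*` — is the model's readout of mechanosensing: it grows
with substrate stiffness.

This package adds an orthogonal elastic spring to the anchorage so the
substrate can carry **residual strain** `ε₀` before any clutch engages,
either as an axial pre-stretch of the orthogonal spring (deformed length
`l' = l(1+ε₀)`) or as a transverse pin offset storing the residual force
`F₀ = k_{sε₀} ε₀ l + k_s x₀`. Sweeping `n_c` at different strain levels
shows `n_c*` shifting to higher values as stored strain energy increases:
the cell perceives a pre-strained matrix as effectively stiffer.

The engine is a first-reaction stochastic simulation: per-clutch
exponential event times (`t = −ln u / k`), earliest event executed, bound
clutches advected with the flow, substrate position re-solved from the
nonlinear two-spring force balance after every event.

## Worked example

```python
import motorclutch as mc

params = mc.ModelParameters(n_c=400, k_s=1.0)     # stiff substrate
trace = mc.run_simulation(params, n_events=20_000, seed=1)
s = mc.summarize(trace)
print(f"mean flow {s.mean_v_f:.1f} nm/s, engaged {s.mean_engaged:.0f}, "
      f"traction {s.mean_traction_force:.0f} pN, cycle {s.mean_cycle_time:.1f} s")
```

prints

```
mean flow 74.4 nm/s, engaged 143, traction 304 pN, cycle 6.8 s
```

— the load-and-fail regime: on average 143 of 400 clutches are bound, they
transmit ~300 pN into the substrate spring, collapse collectively every few
seconds, and hold the retrograde flow well below its unloaded 120 nm/s.
With only 50 clutches the same substrate produces frictional slippage
(sparse engagement, flow near 110 nm/s).

Finding the optimum and its strain response:

```python
grid = mc.log_spaced_grid(10, 200, 25)
soft = mc.ModelParameters(n_c=10, k_s=0.1, strain_mode="axial")
curve = mc.strain_response(soft, [0, 1, 3], "axial", grid,
                           n_events=20_000, seeds=(1, 2, 3))
print(curve.optima.round(1), curve.normalized.round(2))
```

```
[41.7 57.8 74.6] [1.   1.39 1.79]
```

— at zero strain the soft-substrate optimum is ~42 clutches; axial residual
strain 3 shifts it up by ~79%, the strain-stiffening signature.

The same experiments from the shell:

```
motorclutch run   --preset desk --ks 1 --nc 400 --seed 1
motorclutch sweep --preset desk --ks 0.1 --nc-grid 10:200:25
motorclutch strain-response --preset desk --ks 1 --mode transverse --eps 0,0.25,0.5,1
```

Each invocation writes a self-describing output directory (config echo,
tidy CSVs, JSON index with the optima).

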
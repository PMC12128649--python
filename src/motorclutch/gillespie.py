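"""First-reaction stochastic simulation of the clutch ensemble.

Every iteration draws an exponential candidate time for each clutch —
engagement at the constant on-rate for unbound clutches, Bell-law rupture
at the force-dependent off-rate for bound ones — executes the earliest
event, advects the bound clutches with the actin retrograde flow over the
elapsed interval, re-solves the substrate force balance, and updates the
flow from Hill's force-velocity relation.

A *failure* is the event at which the bound count returns to zero; the
substrate then springs back to its rest position and a new loading cycle
begins.  The interval between successive failures is the cycle time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mechanics import (
    BELL_EXPONENT_CAP,
    EquilibriumError,
    Geometry,
    ModelParameters,
    _solve_equilibrium_ms,
    bell_off_rate,
    hill_velocity,
)

__all__ = [
    "ClutchEnsembleState",
    "SimulationTrace",
    "TraceSummary",
    "draw_event_time",
    "step",
    "run_simulation",
    "summarize",
]


@dataclass
class ClutchEnsembleState:
    """Instantaneous ensemble state.

    Disengaged clutches ride with the substrate (``x_c == x_s``); engaged
    ones are carried rearward by the actin flow ``v_f``.
    """

    t: float
    x_s: float
    x_c: np.ndarray
    engaged: np.ndarray
    v_f: float

    @classmethod
    def initial(cls, params: ModelParameters,
                geom: Geometry | None = None) -> "ClutchEnsembleState":
        """All-disengaged rest state.

        Outside transverse mode the substrate rests at zero.  Under
        transverse residual strain the stored force F0 pre-displaces the
        substrate to the baseline solving F0 = F_s(x_s) before any clutch
        binds.
        """
        if geom is None:
            geom = Geometry.from_parameters(params)
        x_s = _solve_equilibrium_ms(0.0, 0, params, geom)
        n = params.n_c
        return cls(t=0.0, x_s=x_s, x_c=np.full(n, x_s, dtype=float),
                   engaged=np.zeros(n, dtype=bool),
                   v_f=hill_velocity(0.0, params))

    @property
    def engaged_count(self) -> int:
        return int(self.engaged.sum())


@dataclass
class SimulationTrace:
    """Per-event time series from one run.

    Arrays are aligned per executed event: ``event_type`` is +1 for an
    engagement, -1 for a rupture; ``x_s``, ``engaged_count``, ``F_s``,
    ``F_clutch`` (summed engaged-clutch force) and ``v_f`` are the values
    immediately after the event.  ``failure_times`` are the instants the
    engaged count returned to zero.
    """

    params: ModelParameters
    seed: int
    t: np.ndarray
    event_type: np.ndarray
    clutch_index: np.ndarray
    x_s: np.ndarray
    engaged_count: np.ndarray
    F_s: np.ndarray
    F_clutch: np.ndarray
    v_f: np.ndarray
    failure_times: np.ndarray
    x_s_rest: float

    @property
    def n_events(self) -> int:
        return self.t.size


@dataclass
class TraceSummary:
    """Averaged outputs of one run (time-weighted unless noted)."""

    mean_v_f: float  # nm/s
    mean_x_s: float  # nm
    mean_cycle_time: float | None  # s; None when no complete cycle occurred
    mean_traction_force: float  # pN, clutch-transmitted load
    mean_engaged: float  # clutches
    mean_clutch_force: float  # pN per engaged clutch
    n_cycles: int


def draw_event_time(rate: float, u: float) -> float:
    """Exponential event time -ln(u)/rate for a uniform variate u in (0,1)."""
    if not rate > 0:
        raise ValueError(f"rate must be strictly positive, got {rate}")
    if not 0.0 < u < 1.0:
        raise ValueError(f"u must lie in the open interval (0,1), got {u}")
    return -math.log(u) / rate


def step(state: ClutchEnsembleState, params: ModelParameters,
         geom: Geometry, rng: np.random.Generator) -> ClutchEnsembleState:
    """Execute one first-reaction event and return the new state.

    Readable single-event reference used by the tests; `run_simulation`
    carries the same update rules in a flat loop for long traces.
    """
    n = params.n_c
    rates = np.empty(n)
    for i in range(n):
        if state.engaged[i]:
            F_c = params.k_c * (state.x_c[i] - state.x_s)
            rates[i] = bell_off_rate(F_c, params)
        else:
            rates[i] = params.k_on
    u = rng.random(n)
    times = -np.log(u) / rates
    winner = int(np.argmin(times))
    dt = float(times[winner])

    x_c = state.x_c.copy()
    engaged = state.engaged.copy()
    x_c[engaged] += state.v_f * dt
    # Disengaged clutches ride with the substrate, so a binding clutch
    # attaches at zero extension at the *event-time* substrate position:
    # solve the balance without it (a zero-force bond does not alter it),
    # then pin the new bond at the solved position.
    binding = not engaged[winner]
    if not binding:
        engaged[winner] = False
    m = int(engaged.sum())
    S = float(x_c[engaged].sum())
    try:
        x_s = _solve_equilibrium_ms(S, m, params, geom, x_guess=state.x_s)
    except EquilibriumError as err:
        err.args = (f"{err.args[0]} at t={state.t + dt:.6g} s",)
        raise
    if binding:
        engaged[winner] = True
        x_c[winner] = x_s
        m += 1
        S += x_s
    x_c[~engaged] = x_s
    F_load = params.k_c * (S - m * x_s)
    return ClutchEnsembleState(t=state.t + dt, x_s=x_s, x_c=x_c,
                               engaged=engaged,
                               v_f=hill_velocity(F_load, params))


def run_simulation(params: ModelParameters, n_events: int,
                   seed: int) -> SimulationTrace:
    """Run ``n_events`` first-reaction events from the all-disengaged state.

    Identical ``(params, n_events, seed)`` reproduce the trace bit for bit.
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    geom = Geometry.from_parameters(params)
    rng = np.random.Generator(np.random.PCG64(seed))
    n = params.n_c

    init = ClutchEnsembleState.initial(params, geom)
    x_s_rest = init.x_s
    x_c = init.x_c.copy()
    engaged = init.engaged.copy()
    t = 0.0
    x_s = init.x_s
    v_f = init.v_f
    m = 0
    S = 0.0

    rec_t = np.empty(n_events)
    rec_type = np.empty(n_events, dtype=np.int8)
    rec_idx = np.empty(n_events, dtype=np.int32)
    rec_xs = np.empty(n_events)
    rec_m = np.empty(n_events, dtype=np.int32)
    rec_Fs = np.empty(n_events)
    rec_Fc = np.empty(n_events)
    rec_vf = np.empty(n_events)
    failures: list[float] = []

    k_c = params.k_c
    k_off = params.k_off
    k_on = params.k_on
    inv_Fb = 1.0 / params.F_b
    use_abs = params.bell_absolute_force
    canonical = params.model_variant == "canonical"
    k_s = params.k_s
    F0 = geom.F0

    for ev in range(n_events):
        # Bell off-rates for engaged clutches, constant on-rate otherwise.
        exponent = np.clip((x_c - x_s) * (k_c * inv_Fb), None, BELL_EXPONENT_CAP)
        if use_abs:
            np.abs(exponent, out=exponent)
            np.clip(exponent, None, BELL_EXPONENT_CAP, out=exponent)
        rates = np.where(engaged, k_off * np.exp(exponent), k_on)
        times = -np.log(rng.random(n)) / rates
        winner = int(np.argmin(times))
        dt = float(times[winner])
        t += dt

        # Advect bound clutches with the flow, then flip the winner.
        if m and v_f:
            adv = v_f * dt
            x_c[engaged] += adv
            S += m * adv
        # A binding clutch attaches at zero extension at the event-time
        # substrate position: solve the balance without it (a zero-force
        # bond leaves it unchanged), then pin the new bond at the root.
        if engaged[winner]:
            engaged[winner] = False
            m -= 1
            S -= float(x_c[winner])
            ev_type = -1
        else:
            ev_type = 1

        if canonical:
            x_s = k_c * S / (k_s + m * k_c)
        elif m == 0 and F0 == 0.0:
            x_s = 0.0
        else:
            try:
                x_s = _solve_equilibrium_ms(S, m, params, geom, x_guess=x_s)
            except EquilibriumError as err:
                err.args = (f"{err.args[0]} at event {ev}, t={t:.6g} s",)
                raise
        if ev_type == 1:
            engaged[winner] = True
            x_c[winner] = x_s
            m += 1
            S += x_s
        x_c[~engaged] = x_s
        if m == 0:
            S = 0.0  # shed accumulated round-off at every renewal
            failures.append(t)

        F_load = k_c * (S - m * x_s)
        v_f = hill_velocity(F_load, params)

        rec_t[ev] = t
        rec_type[ev] = ev_type
        rec_idx[ev] = winner
        rec_xs[ev] = x_s
        rec_m[ev] = m
        rec_Fs[ev] = F_load + F0
        rec_Fc[ev] = F_load
        rec_vf[ev] = v_f

    return SimulationTrace(
        params=params, seed=seed, t=rec_t, event_type=rec_type,
        clutch_index=rec_idx, x_s=rec_xs, engaged_count=rec_m,
        F_s=rec_Fs, F_clutch=rec_Fc, v_f=rec_vf,
        failure_times=np.asarray(failures), x_s_rest=x_s_rest)


def summarize(trace: SimulationTrace, burn_in: float | None = None) -> TraceSummary:
    """Time-weighted averages over the post-transient part of a trace.

    ``burn_in`` is a fraction of total simulated time to discard; when
    ``None`` (default) everything up to and including the first global
    failure is discarded, which removes the deterministic initial loading
    ramp.  Each post-event value is weighted by the waiting time to the
    next event.  Cycle time is the mean spacing of failure times inside
    the averaged window; it is ``None`` (missing) when fewer than two
    failures occurred.
    """
    if trace.n_events == 0:
        raise ValueError("cannot summarize an empty trace")

    t = trace.t
    if burn_in is None:
        if trace.failure_times.size:
            t_start = float(trace.failure_times[0])
        else:
            t_start = 0.0
    else:
        if not 0.0 <= burn_in < 1.0:
            raise ValueError("burn_in fraction must lie in [0, 1)")
        t_start = burn_in * float(t[-1])

    # value after event k holds over [t_k, t_{k+1}); the last event gets no
    # weight (its holding interval is unobserved).
    start = int(np.searchsorted(t, t_start, side="left"))
    if start >= trace.n_events - 1:
        start = 0  # burn-in would discard everything: fall back to full trace
    dt = np.diff(t[start:])
    total = float(dt.sum())
    if total <= 0:
        raise ValueError("trace has no time span to average over")

    def wmean(values: np.ndarray) -> float:
        return float(np.dot(values[start:-1], dt) / total)

    m = trace.engaged_count[start:-1].astype(float)
    with np.errstate(invalid="ignore"):
        per_clutch = np.where(m > 0, trace.F_clutch[start:-1] / np.maximum(m, 1), 0.0)
    failures = trace.failure_times[trace.failure_times >= t_start]
    if failures.size >= 2:
        cycle = float(np.diff(failures).mean())
    else:
        cycle = None
    return TraceSummary(
        mean_v_f=wmean(trace.v_f),
        mean_x_s=wmean(trace.x_s),
        mean_cycle_time=cycle,
        mean_traction_force=wmean(trace.F_clutch),
        mean_engaged=wmean(trace.engaged_count.astype(float)),
        mean_clutch_force=float(np.dot(per_clutch, dt) / total),
        n_cycles=int(failures.size) - 1 if failures.size else 0,
    )
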
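"""Clutch-number sweeps, spline optimum detection and strain-response curves.

The mean retrograde flow is biphasic in the clutch count n_c: small
ensembles slip frictionally (flow near the unloaded velocity), large ones
cycle through load-and-fail with slow flow, and an interior minimum marks
the optimal clutch number — the readout of mechanosensing used throughout.
The optimum is located by cubic-spline interpolation of mean flow against
log(n_c) over a log-spaced grid of clutch counts.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .gillespie import run_simulation, summarize
from .mechanics import ModelParameters

__all__ = [
    "SweepResult",
    "StrainResponseCurve",
    "log_spaced_grid",
    "sweep_nc",
    "optimal_nc",
    "strain_response",
]

logger = logging.getLogger(__name__)

#: points on the dense spline-evaluation grid used to locate the optimum
_SPLINE_EVAL_POINTS = 10_000


@dataclass
class SweepResult:
    """Mean retrograde flow across a grid of clutch counts."""

    nc_grid: np.ndarray
    mean_vf: np.ndarray  # nm/s, averaged over seeds per grid point
    mean_vf_per_seed: np.ndarray  # shape (len(nc_grid), n_seeds)
    events_per_run: int
    seeds: tuple[int, ...]
    params_base: ModelParameters
    optimal_nc: float = field(init=False)
    boundary_optimum: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        self.optimal_nc, self.boundary_optimum = _spline_argmin(
            self.nc_grid, self.mean_vf)

    @property
    def replicate_count(self) -> int:
        return len(self.seeds)


@dataclass
class StrainResponseCurve:
    """Optimal clutch number as a function of residual strain.

    ``normalized`` divides every optimum by the zero-strain optimum;
    ``secant_slopes`` are the slopes of the secant lines joining
    consecutive normalized points — the rate of change of strain sensing.
    """

    eps_levels: np.ndarray
    optima: np.ndarray
    mode: str
    sweeps: list[SweepResult]
    normalized: np.ndarray = field(init=False)
    secant_slopes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        eps = np.asarray(self.eps_levels, dtype=float)
        if eps[0] != 0.0:
            raise ValueError("eps_levels must start at the zero-strain baseline")
        self.normalized = np.asarray(self.optima, dtype=float) / self.optima[0]
        self.secant_slopes = np.diff(self.normalized) / np.diff(eps)


def log_spaced_grid(lo: int, hi: int, n: int) -> np.ndarray:
    """``n`` log-spaced integer clutch counts from ``lo`` to ``hi`` inclusive.

    Values are rounded to integers and deduplicated (log spacing at small
    counts collides after rounding); a warning reports any collision.
    """
    if not (1 <= lo < hi):
        raise ValueError(f"need 1 <= lo < hi, got lo={lo}, hi={hi}")
    if n < 2:
        raise ValueError(f"need n >= 2 grid points, got {n}")
    raw = np.geomspace(lo, hi, n)
    grid = np.unique(np.rint(raw).astype(int))
    if grid.size < n:
        warnings.warn(
            f"log-spaced grid [{lo}, {hi}] with {n} points collapsed to "
            f"{grid.size} distinct integers", stacklevel=2)
    return grid


def _spline_argmin(nc_grid: np.ndarray, mean_vf: np.ndarray) -> tuple[float, bool]:
    """Interior minimum of the cubic spline of mean_vf over log(n_c).

    Returns (optimal n_c, boundary flag).  With fewer than four points no
    cubic spline exists and the discrete argmin is returned.  Ties on the
    dense evaluation grid break toward the smallest n_c.
    """
    nc = np.asarray(nc_grid, dtype=float)
    vf = np.asarray(mean_vf, dtype=float)
    if nc.size < 4:
        i = int(np.argmin(vf))
        return float(nc[i]), i in (0, nc.size - 1)
    log_nc = np.log(nc)
    spline = CubicSpline(log_nc, vf)
    dense = np.linspace(log_nc[0], log_nc[-1], _SPLINE_EVAL_POINTS)
    values = spline(dense)
    i = int(np.argmin(values))
    boundary = i in (0, _SPLINE_EVAL_POINTS - 1)
    if boundary:
        logger.warning("spline minimum sits on the grid boundary "
                       "(n_c = %.4g); no interior optimum", math.exp(dense[i]))
        return math.exp(dense[i]), True
    # local refinement: vertex of the parabola through the three dense
    # neighbours of the minimum (uniform spacing h)
    h = dense[1] - dense[0]
    y0, y1, y2 = values[i - 1:i + 2]
    curvature = y0 - 2.0 * y1 + y2
    x_min = dense[i]
    if curvature > 0:
        shift = 0.5 * h * (y0 - y2) / curvature
        if abs(shift) <= h:
            x_min = dense[i] + shift
    return float(math.exp(x_min)), False


def sweep_nc(params_base: ModelParameters, nc_grid, n_events: int,
             seeds) -> SweepResult:
    """Mean retrograde flow per clutch count, averaged over replicate seeds.

    Each grid point reruns the full stochastic simulation with ``n_m``
    tracking ``n_c`` (the dataclass ties them).  A run that fails is
    logged and excluded from the per-point average rather than silently
    averaged; a grid point with no surviving run raises.
    """
    nc_grid = np.asarray(nc_grid, dtype=int)
    seeds = tuple(int(s) for s in seeds)
    if nc_grid.size == 0:
        raise ValueError("empty n_c grid")
    per_seed = np.full((nc_grid.size, len(seeds)), np.nan)
    for j, nc in enumerate(nc_grid):
        params = params_base.with_nc(int(nc))
        for k, seed in enumerate(seeds):
            try:
                trace = run_simulation(params, n_events, seed)
                per_seed[j, k] = summarize(trace).mean_v_f
            except Exception:
                logger.exception("run failed at n_c=%d seed=%d; excluded",
                                 nc, seed)
        if np.all(np.isnan(per_seed[j])):
            raise RuntimeError(f"all replicate runs failed at n_c={nc}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_vf = np.nanmean(per_seed, axis=1)
    return SweepResult(nc_grid=nc_grid, mean_vf=mean_vf,
                       mean_vf_per_seed=per_seed, events_per_run=n_events,
                       seeds=seeds, params_base=params_base)


def optimal_nc(sweep: SweepResult) -> float:
    """Spline-interpolated clutch count minimizing mean retrograde flow."""
    return sweep.optimal_nc


def strain_response(params_base: ModelParameters, eps_levels, mode: str,
                    nc_grid, n_events: int, seeds) -> StrainResponseCurve:
    """Optimal clutch number across residual-strain levels.

    ``eps_levels`` must include 0 first (or anywhere; levels are sorted),
    since the curve is normalized by the zero-strain optimum.  ``mode``
    selects how the strain is stored: 'axial' pre-stretches the orthogonal
    spring along its axis, 'transverse' offsets its pin sideways.
    """
    eps = np.sort(np.asarray(eps_levels, dtype=float))
    if eps[0] != 0.0:
        raise ValueError("eps_levels must include the zero-strain baseline")
    if mode not in ("axial", "transverse"):
        raise ValueError(f"mode must be 'axial' or 'transverse', got {mode!r}")
    sweeps = []
    optima = []
    for e in eps:
        params = replace(params_base, eps0=float(e), strain_mode=mode)
        result = sweep_nc(params, nc_grid, n_events, seeds)
        sweeps.append(result)
        optima.append(result.optimal_nc)
        logger.info("strain %s eps0=%.3g: optimal n_c = %.4g", mode, e,
                    result.optimal_nc)
    return StrainResponseCurve(eps_levels=eps, optima=np.asarray(optima),
                               mode=mode, sweeps=sweeps)
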
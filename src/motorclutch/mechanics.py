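"""Force laws and force-balance solver for the motor-clutch anchorage.

The anchorage of a clutch ensemble to the substrate is modelled as two
linear springs: the classical horizontal substrate spring ``k_s`` and an
orthogonal spring ``k_s_eps0`` that stores residual strain (pre-strain the
extracellular matrix carries before any clutch engages).  Residual strain
``eps0`` can be imposed

* *axially* — the orthogonal spring is pre-stretched along its own axis to
  a deformed length ``l' = l * (1 + eps0)``; the associated force is taken
  up by the support constraints, so it enters the force balance only
  through the deformed geometry;
* *transversely* — the pin joining the two springs is offset horizontally
  by ``x0``; the stored force ``F0 = k_s_eps0 * eps0 * l + k_s * x0``
  enters the balance additively.

All quantities are in pN, nm and s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "ModelParameters",
    "Geometry",
    "EquilibriumError",
    "bell_off_rate",
    "clutch_force",
    "substrate_force",
    "transverse_offset",
    "residual_force_transverse",
    "solve_equilibrium",
    "hill_velocity",
]

STRAIN_MODES = ("none", "axial", "transverse")
MODEL_VARIANTS = ("canonical", "modified")

#: Cap on the Bell exponent F_c / F_b.  k_off * exp(50) ~ 5e20 1/s: an event
#: at such a rate fires effectively instantly, so capping changes no
#: trajectory while keeping every rate finite.
BELL_EXPONENT_CAP = 50.0

#: Absolute tolerance (nm) on the equilibrium substrate position.
EQUILIBRIUM_XTOL = 1e-10


@dataclass(frozen=True)
class ModelParameters:
    """Kinetic and mechanical constants for one simulation.

    Defaults are the reference parameter set used throughout: motor stall
    force 2 pN, unloaded motor velocity 120 nm/s, bond rupture force 2 pN,
    on-rate 0.3/s, unloaded off-rate 0.1/s, clutch stiffness 0.8 pN/nm.
    The motor count ``n_m`` always equals the clutch count ``n_c``: the
    ensemble stall force grows with the adhesion, which prevents large
    ensembles from stalling the motors outright.
    """

    n_c: int = 50
    F_m: float = 2.0  # pN, single-motor stall force
    v_u: float = 120.0  # nm/s, unloaded motor velocity
    F_b: float = 2.0  # pN, characteristic bond rupture force
    k_on: float = 0.3  # 1/s
    k_off: float = 0.1  # 1/s, unloaded off-rate
    k_c: float = 0.8  # pN/nm, clutch spring constant
    k_s: float = 1.0  # pN/nm, substrate spring constant
    k_s_eps0: float | None = None  # pN/nm, orthogonal spring; defaults to k_s
    l: float = 1000.0  # nm, undeformed orthogonal-spring length
    eps0: float = 0.0  # residual strain, dimensionless
    strain_mode: str = "none"
    model_variant: str = "modified"
    #: apply the Bell law to |F_c| instead of the signed F_c
    bell_absolute_force: bool = False

    def __post_init__(self) -> None:
        if self.k_s_eps0 is None:
            object.__setattr__(self, "k_s_eps0", self.k_s)
        if self.n_c < 1:
            raise ValueError(f"n_c must be >= 1, got {self.n_c}")
        for name in ("F_m", "v_u", "F_b", "k_on", "k_off", "k_c", "k_s",
                     "k_s_eps0", "l"):
            value = getattr(self, name)
            if not (value > 0):
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.eps0 < 0:
            raise ValueError(f"eps0 must be >= 0, got {self.eps0}")
        if self.strain_mode not in STRAIN_MODES:
            raise ValueError(
                f"strain_mode must be one of {STRAIN_MODES}, got {self.strain_mode!r}")
        if self.model_variant not in MODEL_VARIANTS:
            raise ValueError(
                f"model_variant must be one of {MODEL_VARIANTS}, "
                f"got {self.model_variant!r}")
        if self.model_variant == "canonical":
            if self.strain_mode != "none" or self.eps0 != 0:
                raise ValueError(
                    "canonical variant has no orthogonal spring: requires "
                    "strain_mode='none' and eps0=0")
        if self.eps0 > 0 and self.strain_mode == "none":
            raise ValueError("eps0 > 0 requires strain_mode 'axial' or 'transverse'")

    @property
    def n_m(self) -> int:
        """Myosin motor count; always tied to the clutch count."""
        return self.n_c

    @property
    def stall_force(self) -> float:
        """Ensemble stall force n_m * F_m (pN)."""
        return self.n_m * self.F_m

    def with_nc(self, n_c: int) -> "ModelParameters":
        return replace(self, n_c=int(n_c))


@dataclass(frozen=True)
class Geometry:
    """Derived geometry of the orthogonal spring for one strain configuration.

    ``l_prime`` is the deformed spring length entering the substrate-force
    law; ``x0`` the transverse pin offset and ``F0`` the stored residual
    force (both zero outside transverse mode).
    """

    l_prime: float
    x0: float = 0.0
    F0: float = 0.0

    @classmethod
    def from_parameters(cls, params: ModelParameters) -> "Geometry":
        if params.strain_mode == "axial":
            return cls(l_prime=params.l * (1.0 + params.eps0))
        if params.strain_mode == "transverse":
            x0 = transverse_offset(params.eps0, params.l)
            return cls(l_prime=params.l, x0=x0,
                       F0=residual_force_transverse(params.eps0, params))
        return cls(l_prime=params.l)


class EquilibriumError(RuntimeError):
    """Force-balance solver failure, carrying the offending configuration."""

    def __init__(self, message: str, *, x_s_bracket=None, params=None,
                 geom=None, engaged_sum=None, engaged_count=None):
        super().__init__(message)
        self.x_s_bracket = x_s_bracket
        self.params = params
        self.geom = geom
        self.engaged_sum = engaged_sum
        self.engaged_count = engaged_count


def bell_off_rate(F_c: float, params: ModelParameters) -> float:
    """Force-dependent dissociation rate k_off * exp(F_c / F_b) (Bell law).

    The exponent is capped at ``BELL_EXPONENT_CAP`` so extreme clutch loads
    yield a huge but finite rate instead of overflowing.  By default the
    signed clutch force is used (a compressed clutch unbinds more slowly);
    set ``params.bell_absolute_force`` to use ``|F_c|``.
    """
    if params.bell_absolute_force:
        F_c = abs(F_c)
    exponent = min(F_c / params.F_b, BELL_EXPONENT_CAP)
    return params.k_off * math.exp(exponent)


def clutch_force(x_c: float, x_s: float, k_c: float) -> float:
    """Hookean clutch force k_c * (x_c - x_s); positive when stretched ahead."""
    return k_c * (x_c - x_s)


def substrate_force(x_s: float, params: ModelParameters,
                    geom: Geometry | None = None) -> float:
    """Restoring force of the two-spring anchorage at displacement ``x_s``.

    F_s = k_s_eps0 * (sqrt(l'^2 + x_s^2) - l) * x_s / sqrt(l'^2 + x_s^2)
          + k_s * x_s

    The canonical variant has no orthogonal spring and reduces to k_s * x_s.
    """
    if params.model_variant == "canonical":
        return params.k_s * x_s
    if geom is None:
        geom = Geometry.from_parameters(params)
    chord = math.hypot(geom.l_prime, x_s)
    return params.k_s_eps0 * (chord - params.l) * x_s / chord + params.k_s * x_s


def _substrate_stiffness(x_s: float, params: ModelParameters,
                         geom: Geometry) -> float:
    """dF_s/dx_s; always >= k_s for the configurations used here."""
    if params.model_variant == "canonical":
        return params.k_s
    lp2 = geom.l_prime * geom.l_prime
    chord2 = lp2 + x_s * x_s
    chord = math.sqrt(chord2)
    # d/dx [ (chord - l) x / chord ] = 1 - l * lp^2 / chord^3
    return params.k_s_eps0 * (1.0 - params.l * lp2 / (chord2 * chord)) + params.k_s


def transverse_offset(eps0: float, l: float) -> float:
    """Horizontal pin offset x0 producing strain ``eps0`` in a spring of rest
    length ``l``: eps0 = sqrt(l^2 + x0^2)/l - 1, inverted exactly."""
    if eps0 < 0:
        raise ValueError(f"eps0 must be >= 0, got {eps0}")
    if not (l > 0):
        raise ValueError(f"l must be strictly positive, got {l}")
    # (1+eps0)^2 - 1 computed as eps0*(eps0+2) to keep small strains accurate
    return l * math.sqrt(eps0 * (eps0 + 2.0))


def residual_force_transverse(eps0: float, params: ModelParameters) -> float:
    """Stored residual force F0 = k_s_eps0 * eps0 * l + k_s * x0."""
    x0 = transverse_offset(eps0, params.l)
    return params.k_s_eps0 * eps0 * params.l + params.k_s * x0


def hill_velocity(F_load: float, params: ModelParameters) -> float:
    """Actin retrograde flow under load: v_u * (1 - F_load / (n_m * F_m)).

    ``F_load`` is the force the myosin ensemble works against (the summed
    engaged-clutch force).  Clamped to [0, v_u]: the motors neither reverse
    under super-stall load nor exceed their unloaded velocity.
    """
    v = params.v_u * (1.0 - F_load / params.stall_force)
    if v < 0.0:
        return 0.0
    if v > params.v_u:
        return params.v_u
    return v


def _balance_residual(x_s: float, engaged_sum: float, engaged_count: int,
                      params: ModelParameters, geom: Geometry) -> float:
    """F_s(x_s) - F0 - sum_i k_c (x_c,i - x_s); monotone increasing in x_s."""
    clutch_sum = params.k_c * (engaged_sum - engaged_count * x_s)
    return substrate_force(x_s, params, geom) - geom.F0 - clutch_sum


def solve_equilibrium(engaged_positions, params: ModelParameters,
                      geom: Geometry | None = None) -> float:
    """Substrate position balancing clutch, substrate and residual forces.

    Solves F0 + sum_i k_c (x_c,i - x_s) = F_s(x_s) for the engaged clutch
    positions given (F0 = 0 outside transverse mode).  The substrate-minus-
    clutch residual is strictly increasing in x_s with slope at least
    k_s + m k_c, so the root is unique; it is found by a bracketed Newton
    iteration with bisection safeguard.
    """
    engaged = list(engaged_positions)
    m = len(engaged)
    S = math.fsum(engaged)
    if geom is None:
        geom = Geometry.from_parameters(params)
    return _solve_equilibrium_ms(S, m, params, geom)


def _solve_equilibrium_ms(S: float, m: int, params: ModelParameters,
                          geom: Geometry, x_guess: float = 0.0) -> float:
    """Core solver on the sufficient statistics (sum S, count m)."""
    if params.model_variant == "canonical":
        return params.k_c * S / (params.k_s + m * params.k_c)
    if m == 0 and geom.F0 == 0.0:
        return 0.0

    # Bracket the unique root of the monotone residual.
    g0 = _balance_residual(x_guess, S, m, params, geom)
    if g0 == 0.0:
        return x_guess
    span = max(1.0, abs(x_guess))
    if g0 < 0.0:
        lo, glo = x_guess, g0
        hi = x_guess + span
        for _ in range(200):
            ghi = _balance_residual(hi, S, m, params, geom)
            if ghi >= 0.0:
                break
            lo, glo = hi, ghi
            span *= 2.0
            hi += span
        else:
            raise EquilibriumError(
                "failed to bracket equilibrium above the initial guess",
                x_s_bracket=(x_guess, hi), params=params, geom=geom,
                engaged_sum=S, engaged_count=m)
    else:
        hi, ghi = x_guess, g0
        lo = x_guess - span
        for _ in range(200):
            glo = _balance_residual(lo, S, m, params, geom)
            if glo <= 0.0:
                break
            hi, ghi = lo, glo
            span *= 2.0
            lo -= span
        else:
            raise EquilibriumError(
                "failed to bracket equilibrium below the initial guess",
                x_s_bracket=(lo, x_guess), params=params, geom=geom,
                engaged_sum=S, engaged_count=m)

    # Newton within the bracket, bisection when a step leaves it.
    x = 0.5 * (lo + hi)
    for _ in range(100):
        g = _balance_residual(x, S, m, params, geom)
        if g > 0.0:
            hi = x
        elif g < 0.0:
            lo = x
        else:
            return x
        slope = _substrate_stiffness(x, params, geom) + m * params.k_c
        step = g / slope
        x_new = x - step
        if not (lo < x_new < hi):
            x_new = 0.5 * (lo + hi)
        if abs(x_new - x) < EQUILIBRIUM_XTOL:
            return x_new
        x = x_new
    raise EquilibriumError(
        "equilibrium iteration failed to converge",
        x_s_bracket=(lo, hi), params=params, geom=geom,
        engaged_sum=S, engaged_count=m)
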
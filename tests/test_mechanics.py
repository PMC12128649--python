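"""Force laws, geometry and the equilibrium solver."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motorclutch.mechanics import (
    Geometry,
    ModelParameters,
    bell_off_rate,
    clutch_force,
    hill_velocity,
    residual_force_transverse,
    solve_equilibrium,
    substrate_force,
    transverse_offset,
)

BASE = ModelParameters(n_c=50, k_s=1.0)


class TestParameters:
    def test_motor_count_tracks_clutch_count(self):
        assert BASE.n_m == BASE.n_c == 50
        assert BASE.with_nc(400).n_m == 400

    def test_orthogonal_spring_defaults_to_substrate_stiffness(self):
        assert ModelParameters(k_s=0.1).k_s_eps0 == 0.1

    @pytest.mark.parametrize("bad", [
        dict(n_c=0),
        dict(k_s=-1.0),
        dict(eps0=-0.5, strain_mode="axial"),
        dict(strain_mode="diagonal"),
        dict(model_variant="canonical", eps0=1.0, strain_mode="axial"),
        dict(eps0=1.0),  # strain without a strain mode
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelParameters(**bad)


class TestBellOffRate:
    @pytest.mark.parametrize("F_c, expected", [
        (0.0, 0.1),  # exp(0) identity
        (2.0, 0.1 * math.e),
        (4.0, 0.1 * math.e**2),
    ])
    def test_known_values(self, F_c, expected):
        assert bell_off_rate(F_c, BASE) == pytest.approx(expected, rel=1e-12)

    def test_monotone_and_finite_under_extreme_load(self):
        rates = [bell_off_rate(F, BASE) for F in (0, 1, 10, 100, 1e6)]
        assert all(np.isfinite(rates))
        assert all(a <= b for a, b in zip(rates, rates[1:]))

    def test_absolute_force_switch(self):
        p = ModelParameters(n_c=50, k_s=1.0, bell_absolute_force=True)
        assert bell_off_rate(-4.0, p) == pytest.approx(0.1 * math.e**2)
        # literal signed reading: compression slows unbinding
        assert bell_off_rate(-4.0, BASE) == pytest.approx(0.1 * math.e**-2)


class TestClutchForce:
    @pytest.mark.parametrize("x_c, x_s, k_c, expected", [
        (7.0, 7.0, 0.8, 0.0),
        (10.0, 4.0, 0.8, 4.8),
        (0.0, 5.0, 0.8, -4.0),
    ])
    def test_hooke(self, x_c, x_s, k_c, expected):
        assert clutch_force(x_c, x_s, k_c) == pytest.approx(expected)


class TestSubstrateForce:
    def test_zero_displacement_gives_zero_force(self):
        for eps0, mode in [(0.0, "none"), (2.0, "axial")]:
            p = ModelParameters(n_c=50, k_s=1.0, eps0=eps0, strain_mode=mode)
            assert substrate_force(0.0, p) == 0.0

    def test_undeformed_value(self):
        p = ModelParameters(n_c=50, k_s=1.0, l=1000.0)
        expected = 5.0 + (math.sqrt(1000**2 + 25) - 1000) * 5 / math.sqrt(1000**2 + 25)
        assert substrate_force(5.0, p) == pytest.approx(expected, rel=1e-12)
        assert substrate_force(5.0, p) == pytest.approx(5.0000625, rel=1e-7)

    def test_axially_strained_value(self):
        p = ModelParameters(n_c=50, k_s=1.0, l=1000.0, eps0=3.0,
                            strain_mode="axial")
        chord = math.sqrt(4000**2 + 100)
        expected = 10.0 + (chord - 1000.0) * 10.0 / chord
        assert substrate_force(10.0, p) == pytest.approx(expected, rel=1e-12)
        assert substrate_force(10.0, p) == pytest.approx(17.500, abs=5e-4)

    @given(x=st.floats(0.01, 1e4))
    @settings(max_examples=50, deadline=None)
    def test_odd_in_displacement_when_unstrained(self, x):
        p = ModelParameters(n_c=50, k_s=1.0)
        assert substrate_force(-x, p) == pytest.approx(-substrate_force(x, p),
                                                       rel=1e-12)

    @given(x=st.floats(0.0, 1e4), d=st.floats(0.1, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing(self, x, d):
        p = ModelParameters(n_c=50, k_s=1.0, eps0=2.0, strain_mode="axial")
        assert substrate_force(x + d, p) > substrate_force(x, p)

    def test_canonical_variant_is_linear(self):
        p = ModelParameters(n_c=50, k_s=1.0, model_variant="canonical")
        assert substrate_force(123.4, p) == pytest.approx(123.4)


class TestTransverseGeometry:
    def test_offset_values(self):
        assert transverse_offset(0.0, 1000.0) == 0.0
        assert transverse_offset(1.0, 1000.0) == pytest.approx(
            1000.0 * math.sqrt(3.0), rel=1e-12)

    def test_offset_rejects_negative_strain(self):
        with pytest.raises(ValueError):
            transverse_offset(-0.1, 1000.0)

    @pytest.mark.parametrize("eps0", [0.1, 0.25, 0.5, 1.0, 3.0])
    def test_strain_offset_roundtrip(self, eps0):
        l = 1000.0
        x0 = transverse_offset(eps0, l)
        back = math.sqrt(l * l + x0 * x0) / l - 1.0
        assert back == pytest.approx(eps0, rel=1e-12)

    @given(e=st.floats(0.0, 3.0), d=st.floats(0.01, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_offset_monotone_in_strain(self, e, d):
        assert transverse_offset(e + d, 500.0) > transverse_offset(e, 500.0)

    def test_residual_force_values(self):
        p = ModelParameters(n_c=50, k_s=1.0, l=1000.0, eps0=1.0,
                            strain_mode="transverse")
        assert residual_force_transverse(0.0, p) == 0.0
        assert residual_force_transverse(1.0, p) == pytest.approx(
            1000.0 + 1000.0 * math.sqrt(3.0), rel=1e-12)
        # eps0=0.25: 250 + 1000*sqrt(0.5625) = 1000
        assert residual_force_transverse(0.25, p) == pytest.approx(1000.0,
                                                                   rel=1e-12)

    def test_geometry_from_parameters(self):
        axial = ModelParameters(n_c=50, k_s=1.0, l=1000.0, eps0=3.0,
                                strain_mode="axial")
        g = Geometry.from_parameters(axial)
        assert g.l_prime == 4000.0 and g.x0 == 0.0 and g.F0 == 0.0
        trans = ModelParameters(n_c=50, k_s=1.0, l=1000.0, eps0=1.0,
                                strain_mode="transverse")
        g = Geometry.from_parameters(trans)
        assert g.l_prime == 1000.0
        assert g.x0 == pytest.approx(1000.0 * math.sqrt(3.0))
        assert g.F0 > 0


def _bisect_oracle(engaged, params, lo=-1e7, hi=1e7, iters=200):
    """Plain bisection on the force balance; independent of the solver."""
    geom = Geometry.from_parameters(params)

    def g(x):
        return (substrate_force(x, params, geom) - geom.F0
                - sum(clutch_force(xc, x, params.k_c) for xc in engaged))

    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestEquilibrium:
    def test_no_clutches_rest_at_origin(self):
        for mode, eps0 in [("none", 0.0), ("axial", 2.0)]:
            p = ModelParameters(n_c=50, k_s=1.0, eps0=eps0, strain_mode=mode)
            assert solve_equilibrium([], p) == 0.0

    def test_single_clutch_matches_bisection(self):
        p = ModelParameters(n_c=50, k_s=1.0, l=1000.0)
        x = solve_equilibrium([10.0], p)
        assert x == pytest.approx(_bisect_oracle([10.0], p), abs=1e-8)
        # orthogonal term is O(1e-5) here, so close to the linear 8/1.8
        assert x == pytest.approx(4.4444, abs=1e-3)

    def test_canonical_closed_form(self):
        p = ModelParameters(n_c=50, k_s=1.0, model_variant="canonical")
        assert solve_equilibrium([10.0, 20.0], p) == pytest.approx(24 / 2.6,
                                                                   rel=1e-12)

    def test_long_spring_limit_recovers_linear_solution(self):
        # with l >= 1e6 nm and eps0 = 0 the orthogonal term is negligible
        p = ModelParameters(n_c=50, k_s=1.0, l=1e7)
        lin = ModelParameters(n_c=50, k_s=1.0, model_variant="canonical")
        xs = [3.0, 11.0, 40.0]
        assert solve_equilibrium(xs, p) == pytest.approx(
            solve_equilibrium(xs, lin), rel=1e-6)

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_residual_certificate_random_configurations(self, data):
        mode = data.draw(st.sampled_from(["none", "axial", "transverse"]))
        eps0 = 0.0 if mode == "none" else data.draw(st.floats(0.0, 3.0))
        ks = data.draw(st.floats(0.05, 5.0))
        l = data.draw(st.floats(100.0, 5000.0))
        m = data.draw(st.integers(0, 30))
        xs = data.draw(st.lists(st.floats(-50.0, 500.0), min_size=m, max_size=m))
        p = ModelParameters(n_c=50, k_s=ks, l=l, eps0=eps0, strain_mode=mode)
        geom = Geometry.from_parameters(p)
        root = solve_equilibrium(xs, p, geom)
        lhs = geom.F0 + sum(clutch_force(x, root, p.k_c) for x in xs)
        rhs = substrate_force(root, p, geom)
        assert abs(lhs - rhs) < 1e-9 * max(1.0, abs(rhs))

    def test_transverse_preload_displaces_rest_position(self):
        p = ModelParameters(n_c=50, k_s=1.0, l=1000.0, eps0=1.0,
                            strain_mode="transverse")
        rest = solve_equilibrium([], p)
        assert rest > 0
        geom = Geometry.from_parameters(p)
        assert substrate_force(rest, p, geom) == pytest.approx(geom.F0,
                                                               rel=1e-9)


class TestHillVelocity:
    def test_unloaded_and_stall_limits(self):
        p = ModelParameters(n_c=50, k_s=1.0)
        assert hill_velocity(0.0, p) == 120.0
        assert hill_velocity(p.stall_force, p) == 0.0

    def test_half_load(self):
        p = ModelParameters(n_c=50, k_s=1.0)
        assert hill_velocity(50.0, p) == pytest.approx(60.0)

    def test_clamping(self):
        p = ModelParameters(n_c=50, k_s=1.0)
        assert hill_velocity(2 * p.stall_force, p) == 0.0
        assert hill_velocity(-100.0, p) == 120.0
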
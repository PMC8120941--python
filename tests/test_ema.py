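"""Closed-form AB-EMA solvers: shape mappings, unit conversions, inversions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from porethz import ema
from conftest import abema_residual

# strategies for physically valid inputs, kept away from degenerate edges
f_st = st.floats(0.01, 0.95)
ns_st = st.floats(1.05, 4.0)
L_st = st.floats(0.001, 0.999)


class TestShapeMapping:
    @pytest.mark.parametrize(
        "aspect, expected, decimals",
        [(1.0, 1 / 3, 12), (5.0, 0.053, 3), (1 / 5, 0.75, 2)],
    )
    def test_depolarisation_values(self, aspect, expected, decimals):
        assert ema.depolarisation_from_aspect(aspect) == pytest.approx(
            expected, abs=0.5 * 10**-decimals
        )

    @pytest.mark.parametrize(
        "L, expected", [(1 / 3, 1.0), (0.04, 6.0), (0.96, 0.026)]
    )
    def test_aspect_values(self, L, expected):
        assert ema.aspect_from_depolarisation(L) == pytest.approx(expected, abs=5e-4)

    def test_monotone_decreasing(self):
        a = np.linspace(0.05, 20, 200)
        L = ema.depolarisation_from_aspect(a)
        assert np.all(np.diff(L) < 0)

    @given(st.floats(0.02, 50))
    @settings(derandomize=True)
    def test_round_trip(self, aspect):
        L = ema.depolarisation_from_aspect(aspect)
        assert ema.aspect_from_depolarisation(L) == pytest.approx(aspect, abs=1e-12, rel=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            ema.depolarisation_from_aspect(bad)
        with pytest.raises(ValueError):
            ema.aspect_from_depolarisation(bad if bad else 0.0)


class TestAbsorptionConversion:
    def test_zero(self):
        assert ema.kappa_from_alpha(0.0, 1.0) == 0.0

    def test_hand_value(self):
        # 299792458 * 5000 / (4 pi 1e12)
        assert ema.kappa_from_alpha(50.0, 1.0) == pytest.approx(0.11929, abs=5e-5)

    def test_inverse_frequency_scaling(self):
        assert ema.kappa_from_alpha(50.0, 0.2) == pytest.approx(
            5 * ema.kappa_from_alpha(50.0, 1.0)
        )

    def test_round_trip(self):
        assert ema.alpha_from_kappa(ema.kappa_from_alpha(37.0, 0.7), 0.7) == pytest.approx(37.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ema.kappa_from_alpha(-1.0, 1.0)
        with pytest.raises(ValueError):
            ema.kappa_from_alpha(1.0, 0.0)


class TestForwardModel:
    def test_zero_porosity_gives_ns(self):
        assert ema.neff_forward(0.0, 1.86, 0.4) == pytest.approx(1.86, abs=1e-12)

    def test_full_porosity_gives_air(self):
        assert ema.neff_forward(1.0, 1.86, 0.4) == pytest.approx(1.0, abs=1e-12)

    def test_wiener_limit_equivalence(self):
        """At L = 0 and L = 1 the model IS the upper/lower Wiener bound."""
        f, ns = np.meshgrid(np.linspace(0.01, 0.9, 15), np.linspace(1.1, 4, 15))
        upper = np.sqrt(f + (1 - f) * ns**2)
        lower = np.sqrt(1 / (f + (1 - f) / ns**2))
        np.testing.assert_allclose(ema.neff_forward(f, ns, 0.0), upper, atol=1e-12)
        np.testing.assert_allclose(ema.neff_forward(f, ns, 1.0), lower, atol=1e-12)

    def test_monotone_interpolation_in_L(self):
        L = np.linspace(0, 1, 101)
        n = ema.neff_forward(0.3, 1.86, L)
        assert np.all(np.diff(n) < 0)  # strictly decreasing from upper to lower bound
        lo, hi = n[-1], n[0]
        assert np.all((n >= lo - 1e-12) & (n <= hi + 1e-12))

    @given(f_st, ns_st, L_st)
    @settings(derandomize=True)
    def test_satisfies_mixing_equation(self, f, ns, L):
        n = ema.neff_forward(f, ns, L)
        assert abs(abema_residual(f, n, ns, L)) < 1e-10


class TestInversions:
    @given(f_st, ns_st, L_st)
    @settings(derandomize=True)
    def test_ns_round_trip(self, f, ns, L):
        n = ema.neff_forward(f, ns, L)
        assert ema.ns_from_neff(f, n, L) == pytest.approx(ns, abs=1e-10)

    @given(f_st, ns_st, L_st)
    @settings(derandomize=True)
    def test_porosity_round_trip(self, f, ns, L):
        n = ema.neff_forward(f, ns, L)
        assert ema.porosity_from_neff(n, ns, L) == pytest.approx(f, abs=1e-10)

    @given(f_st, ns_st, L_st)
    @settings(derandomize=True)
    def test_depolarisation_round_trip(self, f, ns, L):
        n = ema.neff_forward(f, ns, L)
        assert ema.depolarisation_from_sample(n, ns, f) == pytest.approx(L, abs=1e-10)

    def test_ns_from_wiener_closed_form(self):
        n = np.sqrt(0.2 + 0.8 * 1.86**2)
        assert ema.ns_from_neff(0.2, n, 0.0) == pytest.approx(1.86, abs=1e-12)

    def test_ns_zero_porosity_identity(self):
        assert ema.ns_from_neff(0.0, 1.5, 0.7) == pytest.approx(1.5, abs=1e-14)

    def test_ns_nonphysical_flagged_as_nan(self):
        # n_eff below 1 at moderate porosity implies a solid thinner than air
        assert np.isnan(ema.ns_from_neff(0.5, 1.0, 0.5))

    def test_porosity_endpoints(self):
        assert ema.porosity_from_neff(1.86, 1.86, 0.3) == pytest.approx(0.0, abs=1e-12)
        assert ema.porosity_from_neff(1.0, 1.86, 0.3) == pytest.approx(1.0, abs=1e-12)

    def test_porosity_domain_error(self):
        with pytest.raises(ValueError):
            ema.porosity_from_neff(2.5, 1.86, 0.3)

    def test_L_at_wiener_endpoints(self):
        f, ns = 0.3, 1.86
        upper = np.sqrt(f + (1 - f) * ns**2)
        lower = np.sqrt(1 / (f + (1 - f) / ns**2))
        assert ema.depolarisation_from_sample(upper, ns, f) == 0.0
        assert ema.depolarisation_from_sample(lower, ns, f) == 1.0

    def test_L_outside_bounds_errors(self):
        with pytest.raises(ValueError):
            ema.depolarisation_from_sample(1.9, 1.86, 0.3)

    def test_L_brute_force_scan_oracle(self, rng):
        """Closed-form L agrees with the nearest grid point of a residual
        scan over L in [0, 1] at step 1e-5, on 100 random instances."""
        grid = np.arange(0, 100001) * 1e-5
        for _ in range(100):
            f = rng.uniform(0.02, 0.9)
            ns = rng.uniform(1.1, 3.5)
            L = rng.uniform(0.01, 0.99)
            n = ema.neff_forward(f, ns, L)
            res = np.abs(abema_residual(f, n, ns, grid))
            L_scan = grid[np.argmin(res)]
            L_closed = ema.depolarisation_from_sample(n, ns, f)
            assert abs(L_closed - L_scan) <= 1e-5


class TestComplexSolver:
    def test_reduces_to_real_solver(self):
        f, L = 0.25, 0.4
        n = ema.neff_forward(f, 1.86, L)
        eps = ema.eps_s_from_eps_eff(f, complex(n**2, 0.0), L)
        assert eps.imag == pytest.approx(0.0, abs=1e-12)
        assert np.sqrt(eps.real) == pytest.approx(ema.ns_from_neff(f, n, L), abs=1e-12)

    def test_zero_porosity_identity(self):
        eps = 3.1 - 0.2j
        assert ema.eps_s_from_eps_eff(0.0, eps, 0.5) == pytest.approx(eps)

    def test_forward_substitution_residual(self, rng):
        """Randomised (f, L, eps_s): the recovered solid permittivity
        satisfies the complex mixing equation to < 1e-10."""
        for _ in range(100):
            f = rng.uniform(0.02, 0.9)
            L = rng.uniform(0.0, 1.0)
            eps = complex(rng.uniform(1.1, 9.0), -rng.uniform(0.0, 0.5))
            eps_s = ema.eps_s_from_eps_eff(f, eps, L)
            res = f * (1 - eps) / (eps + L * (1 - eps)) + (1 - f) * (
                eps_s - eps
            ) / (eps + L * (eps_s - eps))
            assert abs(res) < 1e-10

    def test_branch_convention(self):
        n, k = ema.refractive_from_permittivity((1.7 - 0.05j) ** 2)
        assert n == pytest.approx(1.7) and k == pytest.approx(0.05)
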
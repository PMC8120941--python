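"""Wiener bounds, solid-index margins, depolarisation bounds, fit validation."""

import numpy as np
import pytest

from porethz import (
    DepolarisationBounds,
    bound_tangents,
    fit_abema,
    fit_mabema,
    gen_set,
    l_bounds,
    lbounds_demo_sets,
    ns_margins,
    validate_fit,
    wiener_bounds,
    wiener_bounds_multi,
)
from porethz.data import LinearLModel
from conftest import random_consistent_set


class TestWienerBounds:
    def test_converge_to_ns_at_zero_porosity(self):
        lo, hi = wiener_bounds(0.0, 1.86)
        assert lo == hi == pytest.approx(1.86)

    def test_converge_to_air_at_full_porosity(self):
        lo, hi = wiener_bounds(1.0, 1.86)
        assert lo == hi == pytest.approx(1.0)

    def test_upper_closed_form(self):
        _, hi = wiener_bounds(0.3, 2.0)
        assert hi == pytest.approx(np.sqrt(0.3 + 0.7 * 4))

    def test_ordering(self):
        lo, hi = wiener_bounds(np.linspace(0.01, 0.99, 50), 1.86)
        assert np.all(lo < hi)

    def test_multi_single_component_reduction(self):
        lo1, hi1 = wiener_bounds_multi(0.3, [(1.0, 1.86)])
        lo2, hi2 = wiener_bounds(0.3, 1.86)
        assert lo1 == pytest.approx(lo2, abs=1e-12)
        assert hi1 == pytest.approx(hi2, abs=1e-12)

    def test_multi_equal_components_reduction(self):
        lo1, hi1 = wiener_bounds_multi(0.2, [(0.4, 1.7), (0.6, 1.7)])
        lo2, hi2 = wiener_bounds(0.2, 1.7)
        assert (lo1, hi1) == pytest.approx((lo2, hi2), abs=1e-12)

    def test_multi_ordering_randomised(self, rng):
        for _ in range(50):
            x = rng.uniform(0.1, 0.9)
            lo, hi = wiener_bounds_multi(
                rng.uniform(0.05, 0.9),
                [(x, rng.uniform(1.1, 3)), (1 - x, rng.uniform(1.1, 3))],
            )
            assert lo <= hi

    def test_multi_fraction_sum_checked(self):
        with pytest.raises(ValueError):
            wiener_bounds_multi(0.2, [(0.5, 1.7), (0.6, 1.8)])


class TestNsMargins:
    def test_zero_porosity_anchor_pins_ns(self):
        m = ns_margins(np.array([0.0, 0.2]), np.array([1.7, 1.5]))
        assert m.ns_l == pytest.approx(1.7, abs=1e-12)
        assert m.ns_u == pytest.approx(1.7, abs=1e-12)

    def test_containment_on_consistent_set(self):
        ts = gen_set(1.86, 1 / 3, [0.05, 0.15, 0.3, 0.45])
        m = ns_margins(ts)
        assert m.ns_l <= 1.86 <= m.ns_u
        assert m.f1 == 0.05

    def test_margin_attained_at_generating_extreme(self):
        # anchor generated at L = 0 (upper Wiener bound) => lower margin exact
        ts = gen_set(1.86, 0.0, [0.05, 0.2, 0.4])
        m = ns_margins(ts)
        assert m.ns_l == pytest.approx(1.86, abs=1e-12)

    def test_containment_randomised(self, rng):
        for _ in range(100):
            ts, ns, _ = random_consistent_set(rng, n=5)
            m = ns_margins(ts)
            assert m.ns_l - 1e-10 <= ns <= m.ns_u + 1e-10

    def test_upper_margin_undefined_is_flagged(self):
        # anchor porosity so high that even an infinite solid index could
        # explain its n_eff: the series bound is violated and ns_u diverges
        with pytest.raises(ValueError, match="upper margin undefined"):
            ns_margins(np.array([0.6, 0.7]), np.array([2.2, 2.0]))


class TestLBounds:
    def test_anchor_yields_full_interval(self, constant_L_set):
        res = l_bounds(constant_L_set)
        i = np.argmin(res.f)
        assert res.L_l[i] == 0.0 and res.L_u[i] == 1.0

    def test_containment_constant_L(self, constant_L_set):
        res = l_bounds(constant_L_set)
        assert np.all(res.L_l <= 0.5 + 1e-10)
        assert np.all(res.L_u >= 0.5 - 1e-10)

    def test_width_shrinks_with_porosity(self, constant_L_set):
        res = l_bounds(constant_L_set)
        order = np.argsort(res.f)[1:]  # skip the anchor
        width = (res.L_u - res.L_l)[order]
        assert np.all(np.diff(width) < 0)

    def test_containment_randomised(self, rng):
        for _ in range(100):
            ts, _, L = random_consistent_set(rng)
            res = l_bounds(ts)
            assert np.all(res.L_l <= L + 1e-9)
            assert np.all(res.L_u >= L - 1e-9)
            assert np.all((res.L_l >= 0) & (res.L_u <= 1))

    def test_estimator_interface(self, constant_L_set):
        est = DepolarisationBounds().fit(constant_L_set.f, constant_L_set.n_eff)
        assert est.margins_.ns_l <= 1.86 <= est.margins_.ns_u
        df = est.result_.to_frame()
        assert list(df.columns) == ["f", "L_l", "L_u", "flagged"]


class TestTangentsAndValidation:
    def test_constant_L_tangents_below_steepness_threshold(self, constant_L_set):
        """The bounds converge towards the constant L only asymptotically;
        at the top of the porosity range both tangents are already well below
        the 0.25 steepness threshold (and much flatter than for any set with
        |a1| = 0.5)."""
        res = l_bounds(constant_L_set)
        sl, su = bound_tangents(res)
        assert abs(sl) < 0.25 and abs(su) < 0.25

    def test_tangent_signs_follow_gradient(self):
        set1, set2, _ = lbounds_demo_sets()
        sl1, su1 = bound_tangents(l_bounds(set1))
        sl2, su2 = bound_tangents(l_bounds(set2))
        assert sl1 > 0 and su1 > 0  # L increases with porosity
        assert sl2 < 0 and su2 < 0

    def test_constant_L_fit_is_valid(self, constant_L_set):
        fit = fit_abema(constant_L_set)
        report = validate_fit(fit, l_bounds(constant_L_set))
        assert report["valid"]
        assert all(report["per_sample_inside"])

    def test_negative_gradient_set_flags_violations(self):
        _, set2, _ = lbounds_demo_sets()
        fit = fit_abema(set2)
        report = validate_fit(fit, l_bounds(set2))
        assert not report["valid"]
        # the constant fitted L escapes the bounds at intermediate porosities
        assert any(0.05 < f < 0.5 for f in report["violations_at"])

    def test_linear_model_fit_stays_inside_bounds(self):
        set1, _, _ = lbounds_demo_sets()
        fit = fit_mabema(set1)
        bounds = l_bounds(set1)
        inside = validate_fit(fit, bounds)["per_sample_inside"]
        assert all(inside)

    def test_steep_converged_tangents_mark_invalid(self):
        """Both tangents of the negative-gradient set agree in sign and
        exceed the threshold: the bounds have converged onto a steep
        gradient and the constant-L model is flagged."""
        _, set2, _ = lbounds_demo_sets()
        report = validate_fit(fit_abema(set2), l_bounds(set2))
        assert report["steep_tangent"]

    def test_unconverged_tangents_not_steep(self):
        """A consistent constant-L = 1/3 set has tangents of opposite sign
        (the bounds still straddle the flat true gradient); even though one
        magnitude exceeds 0.25 the set must not be flagged steep."""
        ts = gen_set(1.86, 1 / 3, np.arange(1, 11) * 0.05)
        report = validate_fit(fit_abema(ts), l_bounds(ts))
        assert not report["steep_tangent"]
        assert report["valid"]

    def test_tighter_threshold_catches_positive_gradient_set(self):
        set1, _, _ = lbounds_demo_sets()
        report = validate_fit(fit_abema(set1), l_bounds(set1), tangent_threshold=0.2)
        assert report["steep_tangent"]
        assert not report["valid"]
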
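"""Steady probe-bias model: closed-form Bessel solution, finite-difference
oracle agreement, bias linearity and field maps."""

import numpy as np
import pytest

from mdbias import (ProbeParams, alpha, bias_curve, field_map, sink_timescale,
                    solve_steady, solve_steady_fd, to_si)


class TestSinkTimescale:
    def test_basal_components(self, phys):
        ts = sink_timescale(phys)
        assert ts.plasma_part == pytest.approx(750.0, rel=1e-6)
        assert ts.wall_part == pytest.approx(1471.0, rel=1e-3)
        assert ts.A == pytest.approx(ts.plasma_part + ts.wall_part)
        assert ts.screening_length == pytest.approx(0.64e-3, rel=0.01)

    def test_fast_flow_leaves_wall_term(self, phys):
        ts = sink_timescale(phys.with_(F=1e6))
        assert ts.A == pytest.approx(ts.wall_part, rel=1e-6)

    def test_transparent_wall_leaves_plasma_term(self, phys):
        ts = sink_timescale(phys.with_(Dw=1.0))
        assert ts.A == pytest.approx(1.0 / (2 * phys.F), rel=1e-6)


class TestSolveSteady:
    def test_no_gradient_no_flux(self, phys, probe):
        sol = solve_steady(phys, probe, Ci0=probe.Cp)
        assert np.allclose(sol.Ci, probe.Cp)
        assert sol.removal_rate == pytest.approx(0.0, abs=1e-25)

    def test_vanishing_beta_unbiased(self, phys, probe):
        weak = probe.with_(f=probe.f * 1e-8)
        sol = solve_steady(phys, weak, Ci0=4.7)
        assert sol.alpha < 1e-4
        assert sol.Ci_eff == pytest.approx(4.7, abs=1e-3)

    def test_field_monotone_and_far_field(self, phys, probe):
        sol = solve_steady(phys, probe, Ci0=4.7)
        assert np.all(np.diff(sol.Ci) > 0)          # rises toward Ci0
        assert sol.Ci[-1] == pytest.approx(4.7, abs=1e-4)
        assert 0 < sol.alpha < 1

    def test_small_outer_boundary_rejected(self, phys, probe):
        with pytest.raises(ValueError, match="not converged"):
            solve_steady(phys, probe, Ci0=4.7, r2=4 * probe.r1)

    def test_weighted_mean_identity(self, phys, probe):
        sol = solve_steady(phys, probe, Ci0=4.7)
        assert sol.Ci_eff == pytest.approx(
            (1 - sol.alpha) * 4.7 + sol.alpha * probe.Cp, rel=1e-12)


class TestOracleEquivalence:
    @pytest.mark.parametrize("f_conv", [1.0, 4.0, 40.0])
    @pytest.mark.parametrize("beta_mult", [0.25, 1.0, 4.0])
    def test_bessel_vs_finite_difference(self, phys, probe, f_conv, beta_mult):
        """Closed form and FD oracle agree to <0.1% over the flow x beta sweep."""
        p = phys.with_(F=to_si(f_conv, "flow"))
        pr = probe.with_beta_multiplier(beta_mult)
        bessel = solve_steady(p, pr, Ci0=4.7, n=800)
        fd = solve_steady_fd(p, pr, Ci0=4.7, n=4000)
        ci_interp = np.interp(fd.r, bessel.r, bessel.Ci)
        assert np.max(np.abs(ci_interp - fd.Ci)) / 4.7 < 1e-3
        assert fd.alpha == pytest.approx(bessel.alpha, rel=1e-3)


class TestLinearity:
    def test_alpha_independent_of_concentration_pair(self, phys, probe):
        pairs = [(4.7, 2.0), (6.0, 2.0), (3.0, 0.5), (8.0, 4.0)]
        alphas = [solve_steady(phys, probe.with_(Cp=cp), ci0).alpha
                  for ci0, cp in pairs]
        assert np.ptp(alphas) < 1e-8

    def test_alpha_monotone_in_beta(self, phys, probe):
        avals = [alpha(phys, probe.with_beta_multiplier(m))
                 for m in (0.25, 1.0, 4.0)]
        assert avals[0] < avals[1] < avals[2]

    def test_alpha_decreases_with_flow(self, phys, probe):
        avals = [alpha(phys.with_(F=to_si(f, "flow")), probe)
                 for f in (1.0, 4.0, 40.0)]
        assert avals[0] > avals[1] > avals[2]

    def test_bias_curve_is_line_through_cp(self, phys, probe):
        grid = np.linspace(probe.Cp, 8.0, 13)
        curve = bias_curve(phys, probe, grid)
        # passes through (Cp, Cp) with slope 1 - alpha
        assert curve["Ci_eff"][0] == pytest.approx(probe.Cp)
        slopes = np.diff(curve["Ci_eff"]) / np.diff(curve["Ci0"])
        assert np.allclose(slopes, 1 - curve["alpha"], rtol=1e-10)


class TestMassConservation:
    def test_removal_equals_integrated_resupply(self, phys, probe):
        """Probe uptake balances the capillary resupply integral to <0.5%."""
        sol = solve_steady(phys, probe, Ci0=4.7, n=2000)
        resupply = np.trapezoid(sol.gamma() * 2 * np.pi * sol.r, sol.r) \
            * probe.L
        assert resupply == pytest.approx(sol.removal_rate, rel=5e-3)


class TestFieldMap:
    def test_perturbed_region_radius_at_basal(self, phys, probe):
        # the >=5% perturbation region has mm-scale radius
        *_, contours = field_map(phys, probe, Ci0=4.7)
        r95 = contours[0.95]
        assert r95 is not None
        assert 0.5e-3 < r95 < 2.5e-3

    def test_contours_grow_with_ci0(self, phys, probe):
        *_, c_high = field_map(phys, probe, Ci0=4.7)
        *_, c_low = field_map(phys, probe, Ci0=2.9)
        for level in (0.99, 0.95, 0.90):
            assert c_high[level] > c_low[level]

    def test_no_contours_without_gradient(self, phys, probe):
        *_, contours = field_map(phys, probe, Ci0=probe.Cp)
        assert all(v is None for v in contours.values())

    def test_levels_below_wall_fraction_flagged_absent(self, phys, probe):
        sol = solve_steady(phys, probe, Ci0=4.7)
        wall_frac = sol.Ci_eff / 4.7  # ~0.69
        *_, contours = field_map(phys, probe, Ci0=4.7,
                                 levels=(0.95, wall_frac - 0.05))
        assert contours[0.95] is not None
        assert contours[wall_frac - 0.05] is None
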
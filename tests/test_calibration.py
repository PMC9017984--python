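"""Recovery-calibration bias: no-net-flux, internal reference, measured IGC
and its correction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mdbias import (ProbeParams, alpha, correct_igc, dialysate_concentration,
                    internal_reference, measured_igc,
                    measured_igc_closed_form, no_net_flux, solve_steady)


class TestDialysate:
    def test_weighted_mean(self):
        probe = ProbeParams(R0=0.5, Cp=2.0)
        assert dialysate_concentration(probe, 3.3) == pytest.approx(2.65)

    def test_no_gradient_returns_perfusate(self, probe):
        assert dialysate_concentration(probe, probe.Cp) \
            == pytest.approx(probe.Cp)

    def test_perfect_recovery_returns_interstitial(self):
        probe = ProbeParams(R0=1.0, Cp=2.0)
        assert dialysate_concentration(probe, 3.3) == pytest.approx(3.3)


class TestNoNetFlux:
    def test_zero_wait_unbiased(self, phys, probe):
        res = no_net_flux(phys, probe, 4.7, wait_time=0.0)
        assert res.Rm == pytest.approx(probe.R0, rel=1e-10)
        # unbiased recovery but still-biased dialysate: measures Ci_eff
        sol = solve_steady(phys, probe, 4.7)
        assert res.Ci_m == pytest.approx(sol.Ci_eff, rel=1e-6)

    def test_steady_state_slope_gives_biased_recovery(self, phys, probe):
        res = no_net_flux(phys, probe, 4.7)
        a = alpha(phys, probe)
        assert res.Rm == pytest.approx((1 - a) * probe.R0, rel=1e-8)
        # at full steady state both biases cancel: Ci_m = Ci_0
        assert res.Ci_m == pytest.approx(4.7, rel=1e-10)

    def test_points_exactly_collinear(self, phys, probe):
        res = no_net_flux(phys, probe, 4.7, wait_time=300.0)
        cps = np.array([p[0] for p in res.Cd_points])
        cds = np.array([p[1] for p in res.Cd_points])
        coeffs = np.polyfit(cps, cds, 1)
        assert np.max(np.abs(cds - np.polyval(coeffs, cps))) < 1e-8

    def test_grid_independence(self, phys, probe):
        r1 = no_net_flux(phys, probe, 4.7, Cp_grid=(0.0, 1.0, 2.0))
        r2 = no_net_flux(phys, probe, 4.7, Cp_grid=(0.5, 3.0, 5.5, 8.0))
        assert r1.Rm == pytest.approx(r2.Rm, rel=1e-10)

    def test_needs_two_distinct_cp(self, phys, probe):
        with pytest.raises(ValueError, match="two distinct"):
            no_net_flux(phys, probe, 4.7, Cp_grid=(2.0, 2.0))


class TestInternalReference:
    def test_zero_wait_unbiased(self, phys, probe):
        res = internal_reference(phys, probe, Ci0=4.7, wait_time=0.0)
        assert res.Rm == pytest.approx(probe.R0)

    @pytest.mark.parametrize("wait", [120.0, 600.0])
    def test_matches_no_net_flux_at_matched_wait(self, phys, probe, wait):
        """Both calibration techniques are biased the same way (<1%)."""
        nnf = no_net_flux(phys, probe, 4.7, wait_time=wait)
        ir = internal_reference(phys, probe, Ci0=4.7, wait_time=wait)
        assert abs(nnf.Rm - ir.Rm) / nnf.Rm < 0.01

    def test_steady_state_bias_near_alpha(self, phys, probe):
        res = internal_reference(phys, probe, Ci0=4.7)
        a = alpha(phys, probe)
        assert res.Rm == pytest.approx((1 - a) * probe.R0, rel=0.02)
        assert res.Rm < probe.R0


class TestMeasuredIGC:
    def test_two_routes_agree(self, phys, probe):
        a = alpha(phys, probe)
        a_t = 0.3 * a
        ci_m_closed = measured_igc_closed_form(4.7, probe.Cp, a, a_t)
        # route via dialysate and biased recovery
        ci_eff_t = 4.7 * (1 - a_t) + probe.Cp * a_t  # field at sampling time
        cd = dialysate_concentration(probe, 4.7 * (1 - a) + probe.Cp * a)
        rm = (1 - a_t) * probe.R0
        assert measured_igc(cd, rm, probe.Cp) == pytest.approx(ci_m_closed,
                                                               rel=1e-12)

    def test_limits(self):
        a = 0.52
        # calibration at steady state: biases cancel
        assert measured_igc_closed_form(4.7, 2.0, a, a) == pytest.approx(4.7)
        # unbiased calibration: measures the effective concentration
        expected_eff = (1 - a) * 4.7 + a * 2.0
        assert measured_igc_closed_form(4.7, 2.0, a, 0.0) \
            == pytest.approx(expected_eff)

    def test_half_converged_calibration_value(self):
        # hand-evaluated weighted mean for alpha=0.52, alpha_tilde=0.26
        assert measured_igc_closed_form(4.7, 2.0, 0.52, 0.26) \
            == pytest.approx((0.48 * 4.7 + 0.26 * 2.0) / 0.74, rel=1e-12)

    @given(a_t_frac=st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=40, deadline=None)
    def test_measured_value_between_effective_and_true(self, a_t_frac):
        a = 0.52
        a_t = a * a_t_frac
        ci_m = measured_igc_closed_form(4.7, 2.0, a, a_t)
        ci_eff = (1 - a) * 4.7 + a * 2.0
        assert ci_eff - 1e-12 <= ci_m <= 4.7 + 1e-12

    def test_zero_recovery_rejected(self):
        with pytest.raises(ValueError):
            measured_igc(2.5, 0.0, 2.0)


class TestCorrection:
    @given(ci0=st.floats(min_value=2.0, max_value=8.0),
           cp=st.floats(min_value=0.0, max_value=4.0),
           a=st.floats(min_value=0.0, max_value=0.9),
           frac=st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=60, deadline=None)
    def test_round_trip_identity(self, ci0, cp, a, frac):
        a_t = a * frac
        ci_m = measured_igc_closed_form(ci0, cp, a, a_t)
        assert correct_igc(ci_m, cp, a, a_t) == pytest.approx(ci0, rel=1e-10)

    def test_corrects_worked_measurement(self, phys, probe):
        # inverting the forward bias map recovers the true concentration
        sol = solve_steady(phys, probe, 4.7)
        assert correct_igc(sol.Ci_eff, probe.Cp, sol.alpha) \
            == pytest.approx(4.7, rel=1e-10)

    def test_unbiased_passthrough(self):
        assert correct_igc(3.3, 2.0, 0.0) == pytest.approx(3.3)

    def test_total_bias_rejected(self):
        with pytest.raises(ValueError):
            correct_igc(3.3, 2.0, 1.0)
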
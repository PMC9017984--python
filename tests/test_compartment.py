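"""Three-compartment steady model: axial profile, compartmental drops and
the unperturbed interstitial concentration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mdbias import (PhysiologyParams, igc_full, igc_quick_estimate)
from mdbias.compartment import (axial_plasma_profile, cone_radius,
                                endothelial_gradient, interstitial_drop,
                                interstitial_gradient, interstitial_profile,
                                plasma_radial_drop)


class TestConeGeometry:
    def test_endpoints_and_midpoint(self, phys):
        assert cone_radius(0.0, phys) == pytest.approx(28e-6)
        assert cone_radius(1.0, phys) == pytest.approx(22e-6)
        assert cone_radius(0.5, phys) == pytest.approx(25e-6)

    def test_outside_domain_rejected(self, phys):
        with pytest.raises(ValueError):
            cone_radius(1.2, phys)


class TestAxialProfile:
    def test_boundary_values(self, phys):
        assert axial_plasma_profile(0.0, phys) == pytest.approx(phys.Ca)
        # venous end must close the whole-tissue mass balance
        assert axial_plasma_profile(1.0, phys) == pytest.approx(4.8, abs=1e-6)

    def test_no_metabolism_flat(self, phys):
        xi = np.linspace(0, 1, 11)
        c = axial_plasma_profile(xi, phys.with_(M=1e-30))
        assert np.allclose(c, phys.Ca)

    def test_monotone_decreasing(self, phys):
        xi = np.linspace(0, 1, 101)
        c = axial_plasma_profile(xi, phys)
        assert np.all(np.diff(c) < 0)

    @given(mult=st.floats(min_value=0.1, max_value=20.0))
    @settings(max_examples=25, deadline=None)
    def test_conservation_for_any_metabolism(self, mult):
        phys = PhysiologyParams()
        p = phys.with_(M=mult * phys.M)
        drop = p.Ca - axial_plasma_profile(1.0, p)
        assert p.F * drop == pytest.approx(p.M, rel=1e-10)


class TestEndothelialGradient:
    def test_basal_value_near_0p2_mM(self, phys):
        g = endothelial_gradient(phys.rt_mid, phys)
        assert g == pytest.approx(0.196, abs=1e-3)

    def test_linear_in_metabolism(self, phys):
        g1 = endothelial_gradient(phys.rt_mid, phys)
        g15 = endothelial_gradient(phys.rt_mid, phys.with_(M=15 * phys.M))
        assert g15 == pytest.approx(15 * g1, rel=1e-12)
        assert endothelial_gradient(phys.rt_mid, phys.with_(M=1e-30)) \
            == pytest.approx(0.0, abs=1e-12)

    def test_requires_rt_outside_wall(self, phys):
        with pytest.raises(ValueError):
            endothelial_gradient(phys.rw, phys)


class TestInterstitium:
    def test_drop_zero_at_wall_and_tiny_at_rest(self, phys):
        rt = phys.rt_a
        assert interstitial_drop(phys.rw, rt, phys) == pytest.approx(0.0)
        # 25 um beyond the wall at rest: ~5e-4 mM, i.e. ~0.01% of plasma level
        assert interstitial_drop(rt, rt, phys) == pytest.approx(4.8e-4,
                                                                rel=0.02)

    def test_gradient_sign_and_outer_boundary(self, phys):
        rt = phys.rt_mid
        assert interstitial_gradient(rt, rt, phys) == pytest.approx(0.0,
                                                                    abs=1e-15)
        assert interstitial_gradient(phys.rw, rt, phys) < 0

    def test_gradient_matches_numeric_derivative(self, phys):
        rt = phys.rt_mid
        r = np.linspace(phys.rw * 1.2, rt * 0.98, 7)
        h = 1e-9
        num = (interstitial_drop(r + h, rt, phys)
               - interstitial_drop(r - h, rt, phys)) / (2 * h)
        ana = -interstitial_gradient(r, rt, phys)
        assert np.allclose(num, ana, rtol=1e-6)

    def test_profile_continuity_at_wall(self, phys):
        c_wall = interstitial_profile(phys.rw, 0.5, phys)
        c_mid = interstitial_profile(phys.rt_mid, 0.5, phys)
        assert c_wall > c_mid  # glucose flows outward

    @pytest.mark.parametrize("mult", [1, 10, 100])
    def test_drop_below_0p05_mM_even_at_high_metabolism(self, phys, mult):
        p = phys.with_(M=mult * phys.M)
        assert interstitial_drop(p.rt_a, p.rt_a, p) < 5e-2

    def test_out_of_domain_rejected(self, phys):
        with pytest.raises(ValueError):
            interstitial_drop(phys.rp, phys.rt_mid, phys)


class TestIGC:
    def test_quick_estimate_basal(self, phys):
        assert igc_quick_estimate(phys) == pytest.approx(4.70, abs=0.01)

    def test_quick_estimate_no_metabolism_is_arterial(self, phys):
        assert igc_quick_estimate(phys.with_(M=1e-30)) \
            == pytest.approx(phys.Ca)

    def test_full_chain_agrees_with_quick_estimate(self, phys):
        assert abs(igc_full(phys) - igc_quick_estimate(phys)) < 0.05

    def test_plasma_radial_drop_negligible(self, phys):
        assert plasma_radial_drop(phys.rt_mid, phys) < 1e-3

    def test_each_drop_linear_in_metabolism(self, phys):
        p2 = phys.with_(M=2 * phys.M)
        assert plasma_radial_drop(phys.rt_mid, p2) == pytest.approx(
            2 * plasma_radial_drop(phys.rt_mid, phys), rel=1e-12)
        assert interstitial_drop(phys.rt_mid, phys.rt_mid, p2) == \
            pytest.approx(2 * interstitial_drop(phys.rt_mid, phys.rt_mid,
                                                phys), rel=1e-12)
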
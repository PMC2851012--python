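import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cvdom.boundary import (ConfigurationError, DetectorSpec,
                            TotalInternalReflectionError, aperture_mask,
                            apply_boundary, critical_angle, detected_fluence,
                            fresnel_reflectivity, fresnel_table,
                            normalize_profile, outgoing_mask,
                            reflect_ordinate, snell_transmission_angle,
                            transmitted_fluence, trapezoid_weights,
                            uniform_detectors)
from cvdom.medium import build_grid
from cvdom.quadrature import make_ordinates


class TestSnellAndCritical:
    def test_normal_incidence(self):
        assert snell_transmission_angle(0.0, 1.4) == 0.0

    def test_matched_indices_identity(self):
        assert snell_transmission_angle(0.3, 1.0, 1.0) == pytest.approx(0.3)

    def test_oblique_value(self):
        assert snell_transmission_angle(0.3, 1.4) == pytest.approx(
            np.arcsin(1.4 * np.sin(0.3)))

    def test_beyond_critical_raises(self):
        phi_cr = critical_angle(1.4)
        with pytest.raises(TotalInternalReflectionError):
            snell_transmission_angle(phi_cr + 0.01, 1.4)

    @pytest.mark.parametrize("n_m,n_0,expected", [
        (1.0, 1.0, np.pi / 2),
        (1.4, 1.0, np.arcsin(1 / 1.4)),
        (2.0, 1.0, np.pi / 6),
    ])
    def test_critical_angle(self, n_m, n_0, expected):
        assert critical_angle(n_m, n_0) == pytest.approx(expected)

    def test_no_tir_regime_returns_half_pi(self):
        assert critical_angle(1.0, 1.4) == pytest.approx(np.pi / 2)


class TestFresnel:
    def test_unity_beyond_critical(self):
        phi_cr = critical_angle(1.4)
        assert fresnel_reflectivity(phi_cr, 1.4) == 1.0
        assert fresnel_reflectivity(phi_cr + 0.1, 1.4) == 1.0

    def test_matched_normal_incidence_zero(self):
        assert fresnel_reflectivity(0.0, 1.0, 1.0) == pytest.approx(0.0)

    def test_normal_incidence_ratio(self):
        assert fresnel_reflectivity(0.0, 1.4) == pytest.approx(
            ((1.4 - 1) / (1.4 + 1)) ** 2)

    def test_grazing_limit_continuity(self):
        phi_cr = critical_angle(1.4)
        phis = phi_cr - np.logspace(-6, -2, 20)
        R = np.array([fresnel_reflectivity(p, 1.4) for p in phis])
        assert np.all(np.diff(R) < 0)      # increasing toward phi_cr
        # sqrt-type approach to 1: R(phi_cr - 1e-6) is already within ~1e-2
        assert R[0] > 0.98
        assert fresnel_reflectivity(phi_cr, 1.4) == 1.0

    @settings(max_examples=60, derandomize=True)
    @given(phi=st.floats(0, np.pi / 2), n_m=st.floats(1.0, 2.0))
    def test_bounded_unit_interval(self, phi, n_m):
        assert 0.0 <= fresnel_reflectivity(phi, n_m) <= 1.0


class TestReflection:
    def test_bottom_side_negates_eta(self):
        o = make_ordinates(16)
        m = int(np.argmin(np.abs(np.degrees(o.theta) - 210)))
        m_ref = reflect_ordinate(o, m, "bottom")
        assert np.degrees(o.theta[m_ref]) == pytest.approx(
            360 - np.degrees(o.theta[m]))

    def test_left_side_negates_xi(self):
        o = make_ordinates(16)
        for m in range(16):
            m_ref = reflect_ordinate(o, m, "left")
            assert o.xi[m_ref] == pytest.approx(-o.xi[m])
            assert o.eta[m_ref] == pytest.approx(o.eta[m])

    @pytest.mark.parametrize("side", ["bottom", "top", "left", "right"])
    def test_involution(self, side):
        o = make_ordinates(32)
        for m in range(32):
            assert reflect_ordinate(o, reflect_ordinate(o, m, side), side) == m


class TestBoundaryClosure:
    def _outgoing(self, o, side, rng):
        out = np.zeros((3, o.M))
        mask = outgoing_mask(o, side)
        out[:, mask] = rng.random((3, mask.sum()))
        return out

    def test_zero_reflectivity_dark(self, rng):
        o = make_ordinates(16)
        ft = fresnel_table(o, 1.0)  # matched: R = 0 except grazing-exact
        out = self._outgoing(o, "bottom", rng)
        inc = apply_boundary(out, "bottom", o, ft)
        assert np.allclose(inc, 0.0)

    def test_lossless_mirror_closure(self, rng):
        o = make_ordinates(16)
        ft = fresnel_table(o, 1.4)
        # force R = 1 everywhere: total internal reflection closure
        ft = type(ft)(R_x=np.ones(o.M), R_y=np.ones(o.M),
                      phi_cr=ft.phi_cr, n_m=ft.n_m, n_0=ft.n_0)
        out = self._outgoing(o, "top", rng)
        inc = apply_boundary(out, "top", o, ft)
        for m in np.nonzero(~outgoing_mask(o, "top"))[0]:
            assert np.allclose(inc[:, m], out[:, o.mirror_y[m]])

    def test_source_only_injection(self):
        o = make_ordinates(16)
        ft = fresnel_table(o, 1.4)
        src = np.zeros((3, o.M))
        inward = np.nonzero(~outgoing_mask(o, "bottom"))[0]
        src[1, inward[0]] = 7.0
        inc = apply_boundary(np.zeros((3, o.M)), "bottom", o, ft, source=src)
        assert inc[1, inward[0]] == 7.0
        inc[1, inward[0]] = 0.0
        assert np.allclose(inc, 0.0)


class TestFluenceIntegrals:
    def test_total_reflection_transmits_nothing(self):
        o = make_ordinates(16)
        ft = fresnel_table(o, 1.4)
        ft = type(ft)(R_x=np.ones(o.M), R_y=np.ones(o.M),
                      phi_cr=ft.phi_cr, n_m=1.4, n_0=1.0)
        assert transmitted_fluence(np.ones(o.M), ft, o, "top") == 0.0

    def test_isotropic_open_boundary(self):
        # brute-force oracle: sum w_m over the outgoing half-range
        o = make_ordinates(16)
        ft = fresnel_table(o, 1.0)
        mask = outgoing_mask(o, "top")
        expected = 3.0 * (o.w * (1 - ft.R_y) * mask).sum()
        assert transmitted_fluence(np.full(o.M, 3.0), ft, o, "top") == \
            pytest.approx(expected)
        assert expected == pytest.approx(3.0 * np.pi, rel=1e-12)

    def test_single_ordinate_half_reflected(self):
        o = make_ordinates(16)
        m = int(o.quadrant_ordinates(1, 1)[0])
        R_y = np.zeros(o.M)
        R_y[m] = 0.5
        ft = fresnel_table(o, 1.0)
        ft = type(ft)(R_x=ft.R_x, R_y=R_y, phi_cr=ft.phi_cr, n_m=1.0, n_0=1.0)
        rad = np.zeros(o.M)
        rad[m] = 2.0
        assert transmitted_fluence(rad, ft, o, "top") == \
            pytest.approx(0.5 * o.w[m] * 2.0)

    def test_full_aperture_equals_transmitted(self):
        o = make_ordinates(16)
        ft = fresnel_table(o, 1.4)
        rad = np.linspace(0, 1, o.M)
        det = DetectorSpec("top", 0.5, aperture_deg=90.0)
        assert detected_fluence(rad, det, ft, o) == pytest.approx(
            transmitted_fluence(rad, ft, o, "top"))

    def test_aperture_45_admits_four_of_sixteen(self):
        o = make_ordinates(16)
        mask = aperture_mask(o, "top", 45.0)
        assert mask.sum() == 4
        assert np.all(o.eta[mask] >= np.cos(np.radians(45)) - 1e-12)

    def test_detected_never_exceeds_transmitted(self, rng):
        o = make_ordinates(32)
        ft = fresnel_table(o, 1.4)
        rad = rng.random(o.M)
        for ap in (10, 30, 45, 60, 90):
            det = DetectorSpec("left", 0.5, aperture_deg=ap)
            assert detected_fluence(rad, det, ft, o) <= \
                transmitted_fluence(rad, ft, o, "left") + 1e-15

    def test_zero_field_reads_zero(self):
        o = make_ordinates(16)
        ft = fresnel_table(o, 1.4)
        det = DetectorSpec("top", 0.5)
        assert detected_fluence(np.zeros(o.M), det, ft, o) == 0.0

    def test_empty_aperture_is_configuration_error(self):
        o = make_ordinates(16)
        ft = fresnel_table(o, 1.4)
        det = DetectorSpec("top", 0.5, aperture_deg=5.0)  # narrower than any
        with pytest.raises(ConfigurationError):
            detected_fluence(np.ones(o.M), det, ft, o)


class TestDetectors:
    def test_position_snaps_to_face(self):
        grid = build_grid(4.0, 4.0, 0.05, 0.05)
        assert DetectorSpec("top", 2.0).face_index(grid) == 40
        assert DetectorSpec("left", 3.99).face_index(grid) == 79

    def test_out_of_side_rejected(self):
        grid = build_grid(4.0, 4.0, 0.05, 0.05)
        with pytest.raises(ConfigurationError):
            DetectorSpec("top", 4.5).face_index(grid)

    def test_invalid_aperture_rejected(self):
        with pytest.raises(ConfigurationError):
            DetectorSpec("top", 1.0, aperture_deg=120.0)

    def test_uniform_layout_half_insets(self):
        grid = build_grid(4.0, 4.0, 0.05, 0.05)
        dets = uniform_detectors("top", grid, 18)
        pos = np.array([d.position_cm for d in dets])
        assert len(dets) == 18
        assert pos[0] == pytest.approx(4.0 / 36)
        assert np.allclose(np.diff(pos), 4.0 / 18)


class TestNormalizeProfile:
    def test_constant_profile_value(self):
        # direct evaluation: c / ((1/D) c sum(w)) = D / sum(w)
        D = 7
        out = normalize_profile(np.full(D, 3.5))
        assert np.allclose(out, D / trapezoid_weights(D).sum())

    @settings(max_examples=30, derandomize=True)
    @given(k=st.floats(1e-3, 1e3),
           vals=st.lists(st.floats(0.1, 10), min_size=2, max_size=20))
    def test_scale_invariance(self, k, vals):
        v = np.array(vals)
        assert np.allclose(normalize_profile(k * v), normalize_profile(v))

    def test_single_detector_rejected(self):
        with pytest.raises(ValueError):
            normalize_profile(np.array([1.0]))

    def test_all_zero_profile_rejected(self):
        with pytest.raises(ZeroDivisionError):
            normalize_profile(np.zeros(5))


class TestEnergySplit:
    def test_reflected_plus_transmitted_is_unity(self):
        o = make_ordinates(32)
        ft = fresnel_table(o, 1.4)
        for R in (ft.R_x, ft.R_y):
            assert np.allclose(R + (1 - R), 1.0)
            assert np.all((R >= 0) & (R <= 1))

    def test_tir_ordinates_fully_reflective(self):
        o = make_ordinates(16)
        ft = fresnel_table(o, 1.4)
        grazing = np.arccos(np.abs(o.eta)) >= ft.phi_cr
        assert np.all(ft.R_y[grazing] == 1.0)
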
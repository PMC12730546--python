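"""Closed-form plasmonics: resonance condition, conformal geometry, field maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metasers import plasmon as P
from tests.conftest import EPS_FRONT, EPS_SUBSTRATE, SILVER_EPS


class TestOpticalQuality:
    def test_silver_at_785nm(self, silver):
        assert P.optical_quality(silver) == pytest.approx(78.42, abs=0.005)

    @pytest.mark.parametrize(
        "eps, expected",
        [(-1 + 1j, 1.0), (-30 + 0.3j, 100.0)],
    )
    def test_ratio(self, eps, expected):
        assert P.optical_quality(eps) == pytest.approx(expected)

    def test_wrong_time_convention_rejected(self):
        with pytest.raises(P.PassivityError):
            P.optical_quality(-30 - 0.3j)
        with pytest.raises(P.PassivityError):
            P.OpticalMedium(-30 - 0.3j)


class TestDeterminant:
    def test_homogeneous_real(self):
        assert P.det(2.0, 1, 1, 1) == pytest.approx(16.0)

    @given(
        st.complex_numbers(max_magnitude=50, allow_nan=False, allow_infinity=False),
        st.complex_numbers(max_magnitude=50, allow_nan=False, allow_infinity=False),
        st.complex_numbers(max_magnitude=50, allow_nan=False, allow_infinity=False),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_unit_alpha_reduces_algebraically(self, ei, em, ee):
        # at alpha = 1 the determinant collapses to 2 em (ee + ei)
        assert P.det(1.0, ei, em, ee) == pytest.approx(2 * em * (ee + ei), rel=1e-9, abs=1e-9)

    def test_scan_minimum_matches_resonance_ratio(self):
        alphas = np.linspace(1.0, 1.3, 30001)
        mags = np.abs(P.det(alphas, EPS_FRONT, SILVER_EPS, EPS_SUBSTRATE))
        argmin = alphas[np.argmin(mags)]
        assert argmin == pytest.approx(1.1249, rel=0.01)


class TestResonanceRatio:
    def test_symmetric_media(self):
        assert P.alpha_res(-3.0, 1.0, 1.0) == pytest.approx(2.0)

    def test_silver_design(self):
        assert P.alpha_res(-29.8, EPS_FRONT, EPS_SUBSTRATE) == pytest.approx(1.1249, abs=5e-5)

    def test_perfect_conductor_limit(self):
        assert P.alpha_res(-1e9, 1.0, 2.5) == pytest.approx(1.0, abs=1e-6)

    def test_weak_metal_raises(self):
        with pytest.raises(P.NoResonanceError):
            P.alpha_res(-1.5, 1.0, 2.5)

    def test_matches_determinant_argmin(self):
        a_res = P.alpha_res(-29.8, EPS_FRONT, EPS_SUBSTRATE)
        alphas = np.linspace(1.01, 1.3, 20001)
        mags = np.abs(P.det(alphas, EPS_FRONT, SILVER_EPS, EPS_SUBSTRATE))
        assert abs(alphas[np.argmin(mags)] - a_res) / a_res < 0.01


class TestDetResEstimate:
    def test_closed_form_value(self):
        est = P.det_res_estimate(P.OpticalMedium(-30 + 0.3j), 1.0, 1.0)
        assert est == pytest.approx(-1.2j)

    def test_within_factor_two_of_exact(self, silver):
        a_res = P.alpha_res(-29.8, EPS_FRONT, EPS_SUBSTRATE)
        exact = P.det(a_res, EPS_FRONT, SILVER_EPS, EPS_SUBSTRATE)
        est = P.det_res_estimate(silver, EPS_FRONT, EPS_SUBSTRATE)
        ratio = abs(est) / abs(exact)
        assert 0.5 < ratio < 2.0

    def test_lossless_limit_scaling(self):
        hi_q = abs(P.det_res_estimate(P.OpticalMedium(-30 + 1e-4j), 1, 2.5))
        lo_q = abs(P.det_res_estimate(P.OpticalMedium(-30 + 0.1j), 1, 2.5))
        assert hi_q == pytest.approx(lo_q * 1e-3, rel=1e-9)

    def test_low_quality_warns(self):
        with pytest.warns(UserWarning, match="large-Q"):
            P.det_res_estimate(P.OpticalMedium(-3 + 1j), 1, 1)


class TestUniformField:
    def test_homogeneous_is_unity(self):
        m = P.OpticalMedium(2.0 + 0.001j)
        geom = P.CylinderGeometry(1.5, 0.5, (m, m, m))
        assert P.uniform_internal_field(geom) == pytest.approx(1.0, rel=1e-9)

    def test_resonant_enhancement_near_estimate(self, silver):
        a_res = P.alpha_res(-29.8, EPS_FRONT, EPS_SUBSTRATE)
        geom = P.CylinderGeometry(
            a_res, 0.5, (P.OpticalMedium(EPS_FRONT), silver, P.OpticalMedium(EPS_SUBSTRATE))
        )
        exact = abs(P.uniform_internal_field(geom))
        q = P.optical_quality(silver)
        estimate = 2 * EPS_SUBSTRATE * q / (EPS_SUBSTRATE + EPS_FRONT)
        assert exact == pytest.approx(estimate, rel=0.15)

    def test_detuned_alpha_weaker(self, silver):
        media = (P.OpticalMedium(EPS_FRONT), silver, P.OpticalMedium(EPS_SUBSTRATE))
        at_res = abs(
            P.uniform_internal_field(
                P.CylinderGeometry(P.alpha_res(-29.8, EPS_FRONT, EPS_SUBSTRATE), 0.5, media)
            )
        )
        detuned = abs(P.uniform_internal_field(P.CylinderGeometry(3.0, 0.5, media)))
        assert detuned < at_res


class TestDipoleAmplitudeAndMatching:
    def test_homogeneous_no_scattering(self):
        m = P.OpticalMedium(3.0 + 0.01j)
        geom = P.CylinderGeometry(1.4, 0.6, (m, m, m))
        assert abs(P.dipole_amplitude(geom)) < 1e-12
        sol = P.solve_matching_system(geom)
        assert abs(sol.A) < 1e-12

    def test_centered_source_no_dipole(self, silver_geometry):
        assert P.dipole_amplitude(silver_geometry, a=0.0) == 0

    def test_matching_residuals_tiny(self, silver_geometry):
        sol = P.solve_matching_system(silver_geometry)
        pot, dsp = P.matching_residuals(silver_geometry, sol)
        assert pot < 1e-10 and dsp < 1e-10

    @given(
        a=st.floats(min_value=0.05, max_value=0.95),
        alpha=st.floats(min_value=1.01, max_value=3.0),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_closed_form_equals_matching_solver(self, a, alpha, silver):
        geom = P.CylinderGeometry(
            alpha, a, (P.OpticalMedium(EPS_FRONT), silver, P.OpticalMedium(EPS_SUBSTRATE))
        )
        closed = P.dipole_amplitude(geom)
        solved = P.solve_matching_system(geom).A
        assert abs(closed - solved) <= 1e-8 * max(abs(closed), 1.0)


class TestFilmGeometry:
    def test_cylinder_frame_values(self):
        a, alpha = P.geometry_from_fms(400, 80, 15)
        assert a == pytest.approx(np.tanh(0.2 * np.pi), rel=1e-12)
        assert a == pytest.approx(0.5569, abs=5e-5)
        assert alpha == pytest.approx(1.1178, abs=1e-4)

    def test_flat_film_limit(self):
        a, alpha = P.geometry_from_fms(400, 0, 15)
        assert a == 0.0
        assert alpha == pytest.approx(np.exp(2 * np.pi * 15 / 400))

    @given(
        L=st.floats(min_value=100, max_value=1000),
        h=st.floats(min_value=0.1, max_value=200),
        d=st.floats(min_value=0.1, max_value=60),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_round_trip(self, L, h, d):
        a, alpha = P.geometry_from_fms(L, h, d)
        h2, d2 = P.fms_from_geometry(L, a, alpha)
        assert h2 == pytest.approx(h, rel=1e-9)
        assert d2 == pytest.approx(d, rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            P.geometry_from_fms(-400, 80, 15)
        with pytest.raises(ValueError):
            P.fms_from_geometry(400, 1.2, 2.0)


class TestProfiles:
    def test_crest_depression_thickness(self, fig_design):
        x = np.array([0.0, 200.0])
        yu, yb = fig_design.profiles(x)
        assert yu[0] == pytest.approx(51.82, abs=0.005)
        assert yu[1] == pytest.approx(-28.18, abs=0.005)
        assert yu[0] - yu[1] == pytest.approx(80.0, rel=1e-12)
        assert yu[0] - yb[0] == pytest.approx(15.0, rel=1e-9)

    def test_flat_limit(self):
        spec = P.MetasurfaceSpec(400, 0, 15)
        x = np.linspace(0, 800, 100)
        yu, yb = spec.profiles(x)
        assert np.allclose(yu, 0.0)
        assert np.allclose(yb, -400 / (2 * np.pi) * np.log(spec.alpha))

    @given(
        L=st.floats(min_value=200, max_value=800),
        h=st.floats(min_value=1, max_value=150),
        d=st.floats(min_value=1, max_value=40),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_modulation_and_thickness_identities(self, L, h, d):
        spec = P.MetasurfaceSpec(L, h, d)
        x = np.linspace(0, L, 4001)
        yu, yb = spec.profiles(x)
        assert yu.max() - yu.min() == pytest.approx(h, rel=1e-6)
        assert yu[0] - yb[0] == pytest.approx(d, rel=1e-6)
        assert np.all(yu > yb)


class TestFieldIntensity:
    def test_surface_value_is_amplitude_squared(self, fig_design):
        A = 3 - 4j
        val = P.field_intensity(fig_design, A, x=0.0, y=60.0)
        assert val == pytest.approx(25.0 * np.exp(-4 * np.pi * 60 / 400))

    def test_depression_to_crest_ratio(self, fig_design):
        A = 1.0
        bottom = P.field_intensity(fig_design, A, 200.0, -28.18)
        crest = P.field_intensity(fig_design, A, 0.0, 51.82)
        assert bottom / crest == pytest.approx(np.exp(4 * np.pi * 80 / 400), rel=1e-3)
        assert bottom / crest == pytest.approx(12.34, abs=0.01)

    def test_below_surface_masked(self, fig_design):
        assert np.isnan(P.field_intensity(fig_design, 1.0, 0.0, 0.0))

    def test_conformal_map_derivative_oracle(self, fig_design):
        # |dw/dz1|^2 of w = a + exp(i z1) equals the closed-form exp(-2 y1)
        a = fig_design.a
        L = fig_design.L
        rng = np.random.default_rng(7)
        for _ in range(20):
            x1 = rng.uniform(-np.pi, np.pi)
            y1 = rng.uniform(-0.5, 2.0)
            z1 = x1 + 1j * y1
            eps = 1e-6
            dw = (np.exp(1j * (z1 + eps)) - np.exp(1j * (z1 - eps))) / (2 * eps)
            y_nm = y1 * L / (2 * np.pi)
            closed = np.exp(-4 * np.pi * y_nm / L)
            assert abs(abs(dw) ** 2 - closed) <= 1e-6 * max(closed, 1.0)

    def test_field_map_invariants(self, fig_design, silver_geometry):
        A = P.dipole_amplitude(silver_geometry)
        x = np.linspace(0, 800, 81)
        yu, _ = fig_design.profiles(x)
        y = np.linspace(yu.min(), 150, 61)
        fm = P.field_map(fig_design, A, x, y)
        assert np.all(fm.intensity[fm.mask] > 0)
        assert np.allclose(fm.G[fm.mask], fm.intensity[fm.mask] ** 2)
        # intensity grows monotonically toward the depressions (decreasing y)
        col = fm.intensity[:, 0]
        ok = ~np.isnan(col)
        assert np.all(np.diff(col[ok]) < 0)
        # surface maximum sits at the depression bottoms x = L/2 + nL
        surf = np.array(
            [P.field_intensity(fig_design, A, xi, yui) for xi, yui in zip(x, yu)]
        )
        assert x[int(np.argmax(surf))] % 400 == pytest.approx(200.0, abs=11)


class TestDesignHelpers:
    def test_emax_at_bottom(self):
        val = P.emax_estimate(400, 80, 0.0, EPS_FRONT, EPS_SUBSTRATE, 78.42)
        assert val == pytest.approx(16.03, abs=0.01)

    def test_emax_decay_length(self):
        v0 = P.emax_estimate(400, 80, 0.0, EPS_FRONT, EPS_SUBSTRATE, 78.42)
        v1 = P.emax_estimate(400, 80, 400 / (2 * np.pi), EPS_FRONT, EPS_SUBSTRATE, 78.42)
        assert v1 == pytest.approx(v0 / np.e, rel=1e-9)

    def test_emax_flat_film_vanishes(self):
        assert P.emax_estimate(400, 0, 0.0, 1, 2.5, 80) == 0.0

    def test_optimal_thickness_values(self):
        d_max, d_bottom = P.optimal_thickness(400, 80, EPS_FRONT, EPS_SUBSTRATE, -29.8)
        assert d_max == pytest.approx(16.87, abs=0.01)
        assert d_bottom == pytest.approx(np.exp(-0.4 * np.pi) * d_max, rel=1e-12)
        assert d_bottom == pytest.approx(4.80, abs=0.01)

    def test_flat_film_uniform_thickness(self):
        d_max, d_bottom = P.optimal_thickness(400, 0, 1, 2.5, -29.8)
        assert d_bottom == pytest.approx(d_max)

    def test_sers_factor(self):
        assert P.sers_factor(1.0) == 1.0
        assert P.sers_factor(12.34) == pytest.approx(152.3, abs=0.05)
        with pytest.raises(ValueError):
            P.sers_factor(-1.0)

    def test_sers_average_silver_order_of_magnitude(self):
        g = P.sers_average(78.42)
        assert g == pytest.approx(3.78e7, rel=2e-3)
        assert int(np.floor(np.log10(g))) == 7

    def test_sers_average_monotone(self):
        qs = np.linspace(1, 200, 50)
        gs = [P.sers_average(q) for q in qs]
        assert np.all(np.diff(gs) > 0)


class TestResonanceScan:
    def test_silver_scan_optimum(self, silver):
        res = P.resonance_scan(400, 80, silver, EPS_FRONT, EPS_SUBSTRATE, (5, 40))
        # thickness whose alpha hits the analytic resonance ratio
        a = np.tanh(np.pi * 80 / 400)
        d_expected = 400 / (2 * np.pi) * np.log((res.alpha_res - a) / (1 - a))
        assert res.d_opt == pytest.approx(d_expected, abs=2.0)
        assert res.relative_gap < 1e-3
        assert abs(res.det_min_numeric) <= abs(res.det_at_res) + 1e-12

    def test_scan_minimum_is_interior_minimum(self, silver):
        res = P.resonance_scan(400, 80, silver, EPS_FRONT, EPS_SUBSTRATE, (5, 40))
        a = np.tanh(np.pi * 80 / 400)

        def mag(d):
            alpha = a + (1 - a) * np.exp(2 * np.pi * d / 400)
            return abs(P.det(alpha, EPS_FRONT, SILVER_EPS, EPS_SUBSTRATE))

        assert mag(res.d_opt) < mag(res.d_opt - 0.5)
        assert mag(res.d_opt) < mag(res.d_opt + 0.5)

    def test_lossless_metal_reaches_zero(self):
        metal = P.OpticalMedium(-29.8 + 1e-9j)
        res = P.resonance_scan(400, 80, metal, EPS_FRONT, EPS_SUBSTRATE, (5, 40))
        assert abs(res.det_min_numeric) < 1e-6

    def test_boundary_minimum_warns(self, silver):
        with pytest.warns(UserWarning, match="boundary"):
            P.resonance_scan(400, 80, silver, EPS_FRONT, EPS_SUBSTRATE, (30, 40))


def test_validity_report_fields(fig_design, silver):
    rep = P.validity_report(fig_design, silver, 785.0)
    assert rep["L_over_lambda"] == pytest.approx(400 / 785)
    assert rep["skin_depth_nm_estimate"] > 0
    assert "caveat" in rep
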
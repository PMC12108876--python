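"""Closed-form and finite-difference solutions of the tension beam-column."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scolibeam import (
    BeamModelError,
    BeamParameters,
    DegenerateLoadError,
    LoadCase,
    PolynomialProfile,
    effective_axial_load,
    solve_bvp_numeric,
    solve_closed_form,
    total_displacement,
)


class TestLoadCase:
    def test_effective_axial_load(self):
        assert effective_axial_load(LoadCase(P=260.0)) == pytest.approx(260.0)
        assert effective_axial_load(LoadCase(P=260.0, alpha_deg=60.0)) == pytest.approx(130.0)
        assert effective_axial_load(LoadCase(P=0.0, alpha_deg=30.0)) == 0.0

    def test_angle_at_or_beyond_ninety_rejected(self):
        with pytest.raises(BeamModelError):
            LoadCase(P=100.0, alpha_deg=90.0)

    def test_spring_constant_from_sub_curve_length(self, ref_params):
        # ki = 3 EI / Li
        assert ref_params.ki == pytest.approx(3 * 15.1 / 0.042)
        assert ref_params.h == pytest.approx(0.098)


class TestClosedForm:
    def test_boundary_conditions_hold(self, ref_profile, ref_params):
        sol = solve_closed_form(ref_profile, ref_params, LoadCase(P=150.0, Q=80.0))
        h = ref_params.h
        assert abs(sol.correction(-h)) < 1e-9
        assert abs(sol.correction(h)) < 1e-9
        assert abs(sol.correction_curvature(-h)) < 1e-6
        assert abs(sol.correction_curvature(h)) < 1e-6

    def test_required_load_nulls_displacement_at_station(self, ref_profile, ref_params):
        """At the published total load the displacement at x = 0.095 m is
        essentially zero."""
        sol = solve_closed_form(ref_profile, ref_params, LoadCase(P=35351.0))
        assert abs(sol.total(0.095)) < 1e-5

    def test_specialised_solution_constants(self, ref_profile, ref_params):
        """The general construction reproduces the constants of the
        published specialisation for this profile and EI = 15.1."""
        a3, a2 = ref_profile.coefficients[0], ref_profile.coefficients[1]
        EI, h = ref_params.EI, ref_params.h
        assert 2 * a2 == pytest.approx(-7.1109)
        assert 6 * a3 * h == pytest.approx(-19.91297868)
        assert 6 * a3 * EI == pytest.approx(-3068.224266)
        assert 2 * a2 * EI == pytest.approx(-107.37459)
        # and the cosh/sinh amplitudes follow those constants:
        P = 150.0
        sol = solve_closed_form(ref_profile, ref_params, LoadCase(P=P))
        k = np.sqrt(P / EI)
        assert sol.c_cosh * k**2 * np.cosh(k * h) == pytest.approx(2 * a2)
        assert sol.c_sinh * k**2 * np.sinh(k * h) == pytest.approx(6 * a3 * h)

    def test_zero_axial_load_degenerates(self, ref_profile, ref_params):
        with pytest.raises(DegenerateLoadError):
            solve_closed_form(ref_profile, ref_params, LoadCase(P=0.0, Q=100.0))

    def test_quartic_profile_rejected(self, ref_params):
        quartic = PolynomialProfile((1.0, 0.0, 0.0, 0.0, 0.0))
        with pytest.raises(BeamModelError, match="degree"):
            solve_closed_form(quartic, ref_params, LoadCase(P=100.0))

    def test_overflow_guard(self, ref_profile, ref_params):
        with pytest.raises(BeamModelError, match="guard"):
            solve_closed_form(ref_profile, ref_params, LoadCase(P=1e12))

    def test_station_outside_span_rejected(self, ref_profile, ref_params):
        sol = solve_closed_form(ref_profile, ref_params, LoadCase(P=100.0))
        with pytest.raises(BeamModelError):
            total_displacement(sol, 0.2)

    def test_correction_vanishes_for_tiny_load(self, ref_profile, ref_params):
        sol = solve_closed_form(ref_profile, ref_params, LoadCase(P=1e-3))
        xs = np.linspace(-ref_params.h, ref_params.h, 101)
        assert np.max(np.abs(sol.correction(xs))) < 1e-6

    def test_apex_displacement_decreases_monotonically_with_load(
        self, ref_profile, ref_params
    ):
        """Higher traction pulls the curve toward zero (no oscillation —
        tension, not buckling)."""
        Ps = np.geomspace(10.0, 1e5, 25)
        ys = [
            abs(solve_closed_form(ref_profile, ref_params, LoadCase(P=P)).total(0.035))
            for P in Ps
        ]
        assert all(b < a for a, b in zip(ys, ys[1:]))
        assert ys[-1] < 0.05 * ys[0]

    def test_stronger_load_gives_smaller_apex_displacement(self, ref_profile, ref_params):
        y250 = solve_closed_form(ref_profile, ref_params, LoadCase(P=250.0)).total(0.035)
        y50 = solve_closed_form(ref_profile, ref_params, LoadCase(P=50.0)).total(0.035)
        assert abs(y250) < abs(y50)

    def test_ends_pinned_to_initial_displacement(self, ref_profile, ref_params):
        sol = solve_closed_form(ref_profile, ref_params, LoadCase(P=150.0, Q=80.0))
        h = ref_params.h
        assert sol.total(-h) == pytest.approx(ref_profile(-h), abs=1e-9)
        assert sol.total(h) == pytest.approx(ref_profile(h), abs=1e-9)

    @given(Q=st.floats(0.0, 200.0))
    def test_correction_is_linear_in_lateral_load(self, Q, ref_profile, ref_params):
        """y1(P, Q) - y1(P, 0) scales linearly in Q at fixed P."""
        P = 150.0
        x = 0.02
        base = solve_closed_form(ref_profile, ref_params, LoadCase(P=P)).correction(x)
        at_Q = solve_closed_form(ref_profile, ref_params, LoadCase(P=P, Q=Q)).correction(x)
        at_2Q = solve_closed_form(
            ref_profile, ref_params, LoadCase(P=P, Q=2 * Q)
        ).correction(x)
        assert at_2Q - base == pytest.approx(2 * (at_Q - base), abs=1e-12)

    def test_symmetric_profile_gives_even_solution(self, ref_params):
        sym = PolynomialProfile((0.0, -3.5, 0.0, 0.03))
        sol = solve_closed_form(sym, ref_params, LoadCase(P=150.0, Q=80.0))
        xs = np.linspace(0.0, ref_params.h, 25)
        np.testing.assert_allclose(sol.total(xs), sol.total(-xs), atol=1e-14)


class TestNumericOracle:
    @pytest.mark.parametrize("P", [50.0, 150.0, 250.0, 35351.0])
    @pytest.mark.parametrize("Q", [0.0, 80.0, 162.5])
    def test_agrees_with_closed_form(self, P, Q, ref_profile, ref_params):
        cf = solve_closed_form(ref_profile, ref_params, LoadCase(P=P, Q=Q))
        nm = solve_bvp_numeric(ref_profile, ref_params, LoadCase(P=P, Q=Q), 2001)
        diff = np.abs(np.asarray(cf.total(nm.grid_x)) - np.asarray(nm.total(nm.grid_x)))
        assert np.max(diff) < 1e-6

    def test_pure_lateral_limit_matches_textbook_deflection(self, ref_params):
        """With P = 0 the equation reduces to simple bending; the midspan
        deflection of a pinned beam under uniform load is 5 q l^4/(384 EI)."""
        straight = PolynomialProfile((0.0,))
        Q, EI, l = 162.5, ref_params.EI, ref_params.L
        nm = solve_bvp_numeric(straight, ref_params, LoadCase(P=0.0, Q=Q), 2001)
        expected = -5 * Q * l**4 / (384 * EI)
        assert nm.correction(0.0) == pytest.approx(expected, rel=1e-3)

    def test_second_order_convergence(self, ref_profile, ref_params):
        """Halving the grid spacing reduces the error against the closed
        form by about 4x (on grids coarse enough that truncation, not
        round-off, dominates)."""
        load = LoadCase(P=150.0, Q=80.0)
        cf = solve_closed_form(ref_profile, ref_params, load)
        errs = []
        for n in (251, 501):
            nm = solve_bvp_numeric(ref_profile, ref_params, load, n)
            errs.append(
                np.max(
                    np.abs(
                        np.asarray(cf.total(nm.grid_x)) - np.asarray(nm.total(nm.grid_x))
                    )
                )
            )
        ratio = errs[0] / errs[1]
        assert 3.0 < ratio < 5.0

    def test_cross_checks_published_required_load(self, ref_profile, ref_params):
        nm = solve_bvp_numeric(ref_profile, ref_params, LoadCase(P=35351.0), 2001)
        assert abs(nm.total(0.095)) < 1e-5

    def test_grid_validation(self, ref_profile, ref_params):
        with pytest.raises(BeamModelError):
            solve_bvp_numeric(ref_profile, ref_params, LoadCase(P=100.0), 200)
        with pytest.raises(BeamModelError):
            solve_bvp_numeric(ref_profile, ref_params, LoadCase(P=100.0), 101)

    def test_spatially_varying_lateral_load(self, ref_profile, ref_params):
        """A hat-shaped Q(x) with the same mean as a uniform load deflects
        the beam more at midspan (load concentrated where it matters)."""
        h = ref_params.h
        straight = PolynomialProfile((0.0,))
        uniform = solve_bvp_numeric(straight, ref_params, LoadCase(P=100.0, Q=100.0), 1001)
        hat = solve_bvp_numeric(
            straight,
            ref_params,
            LoadCase(P=100.0, Q=0.0),
            1001,
            Q_func=lambda x: 200.0 * (1 - np.abs(x) / h),
        )
        assert abs(hat.correction(0.0)) > abs(uniform.correction(0.0))


class TestSpringBoundaryMode:
    def test_spring_mode_agrees_with_its_numeric_counterpart(self, ref_profile):
        params = BeamParameters(EI=15.1, L=0.196, Li=0.042, ks=5.0)
        load = LoadCase(P=150.0, Q=80.0)
        cf = solve_closed_form(ref_profile, params, load, spring_bc=True)
        nm = solve_bvp_numeric(ref_profile, params, load, 2001, spring_bc=True)
        xs = np.linspace(-params.h, params.h, 41)
        assert np.max(np.abs(np.asarray(cf.total(xs)) - np.asarray(nm.total(xs)))) < 1e-6

    def test_spring_mode_changes_the_solution(self, ref_profile):
        params = BeamParameters(EI=15.1, L=0.196, Li=0.042, ks=50.0)
        load = LoadCase(P=150.0)
        default = solve_closed_form(ref_profile, params, load)
        sprung = solve_closed_form(ref_profile, params, load, spring_bc=True)
        assert abs(default.total(0.035) - sprung.total(0.035)) > 1e-8
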
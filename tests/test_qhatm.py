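"""q-HATM recursion: printed low-order terms, classical limits, diagnostics."""

import math

import numpy as np
import pytest

from fracsmoke import fracseries as fs
from fracsmoke.oracles import rk4_solve, smoking_system_spec, taylor_oracle
from fracsmoke.qhatm import (
    BracketShapeError,
    DivergenceError,
    SolverConfig,
    assemble,
    extract_bracket_scalar,
    h_curve,
    residual,
    solve,
)
from fracsmoke.smoking_model import COMPARTMENTS, InitialState, ModelParams

from conftest import random_initial_state, random_rates

FIRST_ORDER = {"M": 8.136, "L": -5.560, "N": -2.130, "O": 0.980, "P": -0.970}
SECOND_ORDER = {"M": -0.144588, "L": -0.373880, "N": 0.484830, "O": 0.062420,
                "P": -0.050940}

ZERO_MODEL = ModelParams(theta=0, chi1=0, chi2=0, gamma=0, rho=0, lam=0, beta=0,
                         mu=0, sigma=0)


def default_solution(chi=1.0, h=-1.0, n=1, order=6, params=None, init=None):
    return solve(
        params or ModelParams(),
        init or InitialState(),
        SolverConfig(chi=chi, kcap=1.0, h=h, n=n, order=order),
    )


class TestConfigValidation:
    def test_h_zero_rejected(self):
        with pytest.raises(ValueError):
            SolverConfig(h=0.0)

    @pytest.mark.parametrize("kwargs", [
        {"chi": 0.0}, {"chi": 1.2}, {"n": 0}, {"order": 0}, {"kcap": -1.0},
    ])
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SolverConfig(**kwargs)


class TestLowOrderTerms:
    @pytest.mark.parametrize("chi", [0.4, 0.7, 1.0])
    def test_first_term_has_printed_bracket_structure(self, chi):
        sol = default_solution(chi=chi)
        # omega_1 = s*h*{(1-chi)e_0 + chi e_1} with h=-1
        for c, name in enumerate(COMPARTMENTS):
            s = FIRST_ORDER[name]
            coeffs = sol.terms[1][c].coeffs
            assert coeffs[0] == pytest.approx(-s * (1 - chi), abs=1e-12)
            assert coeffs[1] == pytest.approx(-s * chi, abs=1e-12)
            assert all(c_ == 0 for c_ in coeffs[2:])

    @pytest.mark.parametrize("chi", [0.5, 1.0])
    def test_second_term_is_pure_integral_when_carry_vanishes(self, chi):
        sol = default_solution(chi=chi)  # n=1, h=-1 so n+h=0
        for c, name in enumerate(COMPARTMENTS):
            s = SECOND_ORDER[name]
            expected = [
                s * (1 - chi) ** 2,
                s * 2 * chi * (1 - chi),
                s * chi**2,
            ]
            assert sol.terms[2][c].coeffs[:3] == pytest.approx(expected, abs=1e-9)

    def test_zero_model_is_a_fixed_point(self):
        sol = solve(ZERO_MODEL, InitialState(0, 0, 0, 0, 0),
                    SolverConfig(chi=0.8, h=-1.0, n=1, order=5))
        for term in sol.terms:
            for series in term:
                assert all(c == 0 for c in series.coeffs)
        assert sol.evaluate([0.0, 1.0]) == pytest.approx(np.zeros((2, 5)), abs=0)

    def test_order_degree_bound(self):
        sol = default_solution(chi=0.7, order=8)
        for r, term in enumerate(sol.terms):
            for series in term:
                assert all(c == 0 for c in series.coeffs[r + 1:])

    def test_initial_terms_equal_initial_conditions(self):
        sol = default_solution(chi=0.6)
        assert [s.coeffs[0] for s in sol.terms[0]] == [68, 40, 30, 20, 15]


class TestBracketExtraction:
    def test_first_order_scalars(self):
        sol = default_solution()
        for name, value in FIRST_ORDER.items():
            assert extract_bracket_scalar(sol, name, 1) == pytest.approx(value, abs=1e-9)

    def test_second_order_scalars(self):
        sol = default_solution()
        for name, value in SECOND_ORDER.items():
            assert extract_bracket_scalar(sol, name, 2) == pytest.approx(value, abs=1e-9)

    def test_extraction_is_chi_invariant(self):
        # the scalar multiplies a chi-dependent bracket; the projection must
        # recover the same number at any fractional order
        for chi in (0.3, 0.85):
            sol = default_solution(chi=chi)
            assert extract_bracket_scalar(sol, "M", 1) == pytest.approx(8.136, abs=1e-9)
            assert extract_bracket_scalar(sol, "N", 2) == pytest.approx(0.484830, abs=1e-9)

    def test_carry_is_removed_for_general_h(self):
        sol = default_solution(h=-0.5)  # n+h = 0.5, carry nonzero
        assert extract_bracket_scalar(sol, "M", 2) == pytest.approx(-0.144588, abs=1e-9)

    def test_zero_model_scalars_vanish(self):
        sol = solve(ZERO_MODEL, InitialState(0, 0, 0, 0, 0),
                    SolverConfig(chi=0.8, h=-1.0, n=1, order=3))
        assert extract_bracket_scalar(sol, "L", 1) == 0.0

    def test_shape_violation_detected(self):
        sol = default_solution(order=3)
        doctored = fs.FracBasisSeries(
            chi=sol.config.chi, kcap=1.0, coeffs=(0.0, 1.0, 5.0, 0.0)
        )
        sol.terms[1] = (doctored,) + sol.terms[1][1:]
        with pytest.raises(BracketShapeError):
            extract_bracket_scalar(sol, "M", 1)

    def test_higher_orders_not_supported(self):
        sol = default_solution()
        with pytest.raises(ValueError):
            extract_bracket_scalar(sol, "M", 3)


class TestClassicalLimit:
    def test_taylor_equivalence_default_model(self):
        # chi=1, K=1, n=1, h=-1: assembled coefficients are the Maclaurin
        # coefficients of the classical solution, c_r = r! * a_r
        R = 8
        sol = default_solution(order=R)
        a = taylor_oracle(smoking_system_spec(), R)
        for c in range(5):
            got = sol.assembled[c].coeffs
            expected = [math.factorial(r) * a[r, c] for r in range(R + 1)]
            assert got == pytest.approx(expected, rel=1e-9, abs=1e-9)

    def test_taylor_equivalence_random_models(self, rng):
        R = 6
        for _ in range(10):
            p = random_rates(rng)
            ic = random_initial_state(rng)
            sol = default_solution(order=R, params=p, init=ic)
            a = taylor_oracle(smoking_system_spec(p, ic), R)
            for c in range(5):
                expected = [math.factorial(r) * a[r, c] for r in range(R + 1)]
                assert sol.assembled[c].coeffs == pytest.approx(
                    expected, rel=1e-9, abs=1e-9
                )

    def test_homotopy_denominator_consistency(self):
        # (n, h) = (2, -2) and (1, -1) both have vanishing carry and must
        # assemble to the same chi=1 Taylor polynomial
        sol_1 = default_solution(n=1, h=-1.0, order=6)
        sol_2 = default_solution(n=2, h=-2.0, order=6)
        for c in range(5):
            assert sol_2.assembled[c].coeffs == pytest.approx(
                sol_1.assembled[c].coeffs, rel=1e-9, abs=1e-9
            )

    def test_trajectory_matches_rk4(self):
        t = np.linspace(0, 1, 41)
        sol = default_solution(order=10)
        ref = rk4_solve(smoking_system_spec(), t, step=1e-3)
        assert np.max(np.abs(sol.evaluate(t) - ref)) < 1e-5

    def test_initial_slopes_have_expected_signs(self):
        # M decreasing, L increasing, N increasing, O decreasing, P increasing
        sol = default_solution(order=6)
        t = np.array([0.0, 1e-3])
        traj = sol.evaluate(t)
        slopes = traj[1] - traj[0]
        assert np.sign(slopes) == pytest.approx([-1, 1, 1, -1, 1])


class TestSolverBehaviour:
    def test_deterministic_bit_identical(self):
        a = default_solution(chi=0.77, order=7)
        b = default_solution(chi=0.77, order=7)
        for ta, tb in zip(a.terms, b.terms):
            for sa, sb in zip(ta, tb):
                assert sa.coeffs == sb.coeffs

    def test_divergence_reported_with_location(self):
        with pytest.raises(DivergenceError) as exc:
            default_solution(h=10.0, order=15)
        assert exc.value.compartment in COMPARTMENTS
        assert 1 <= exc.value.order <= 15

    def test_assemble_plain_sum_at_n_one(self):
        sol = default_solution(order=4)
        manual = np.zeros(5)
        t = 0.5
        for term in sol.terms:
            manual += [fs.evaluate(s, t) for s in term]
        assert sol.evaluate([t])[0] == pytest.approx(manual, rel=1e-12)


class TestHCurve:
    def test_h_curve_contains_solve_composition(self):
        params, init = ModelParams(), InitialState()
        df = h_curve(params, init, chi=1.0, order=4, t_probe=0.1,
                     h_grid=[-1.5, -1.0, -0.5])
        sol = default_solution(order=4)
        row = df[df.h == -1.0].iloc[0]
        expected = sol.evaluate([0.1])[0]
        assert [row[c] for c in COMPARTMENTS] == pytest.approx(expected, rel=1e-12)

    def test_plateau_near_minus_one(self):
        # admissible h region: values at h=-0.9 and h=-1.1 bracket h=-1 closely
        params, init = ModelParams(), InitialState()
        df = h_curve(params, init, chi=1.0, order=8, t_probe=0.1,
                     h_grid=[-1.1, -1.0, -0.9])
        m = df["M"].to_numpy()
        assert np.max(np.abs(m - m[1])) < 1e-3


class TestResidual:
    def test_zero_model_residual_is_zero(self):
        sol = solve(ZERO_MODEL, InitialState(0, 0, 0, 0, 0),
                    SolverConfig(chi=0.9, h=-1.0, n=1, order=4))
        rep = residual(sol, np.linspace(0, 1, 5))
        assert np.all(rep.residuals == 0)

    def test_residual_non_increasing_with_order(self):
        vals = []
        for R in (2, 4, 6):
            sol = default_solution(chi=0.9, order=R)
            vals.append(residual(sol, [0.2]).residuals[0])
        for lo, hi in zip(vals[1:], vals[:-1]):
            assert np.all(lo <= hi + 1e-12)

    def test_residual_reaches_round_off_for_large_order(self):
        sol = default_solution(chi=0.9, order=14)
        rep = residual(sol, np.linspace(0, 0.2, 5))
        assert np.max(rep.residuals) < 1e-8

    def test_negative_undershoot_is_flagged_not_clamped(self):
        # an aggressively truncated series on a long window can undershoot;
        # build a model where O starts negative-trending and check reporting
        sol = default_solution(order=2)
        rep = residual(sol, np.linspace(0, 50, 20))
        assert set(rep.min_values) == set(COMPARTMENTS)
        assert rep.negative_compartments() == [
            name for name, v in rep.min_values.items() if v < 0
        ]
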
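import numpy as np
import pytest

from cigrowth.growth_laws import (GrowthLawSpec, genlogistic_condition,
                                  genlogistic_solution, gompertz_condition,
                                  gompertz_solution, rhs, solve)


class TestRhs:
    def test_gen_logistic_values(self):
        spec = GrowthLawSpec("gen_logistic", lam=1.0, delta=0.0, omega_bar=2.0)
        assert rhs(spec, 0.5) == pytest.approx(0.375)
        assert rhs(spec, 1.0) == pytest.approx(0.0)

    def test_gompertz_at_saturation(self):
        spec = GrowthLawSpec("gompertz", lam=0.3, delta=0.02, omega_bar=5.0)
        assert rhs(spec, 1.0) == pytest.approx(-0.02)

    def test_gompertz_rejects_nonpositive_density(self):
        spec = GrowthLawSpec("gompertz", lam=0.1, omega_bar=1.0)
        with pytest.raises(ValueError):
            rhs(spec, 0.0)

    def test_radial_count_form(self):
        spec = GrowthLawSpec("radial", lam=0.1, delta=0.01, d=2)
        n = 100.0
        assert rhs(spec, n) == pytest.approx(0.1 * 2 * 10.0 - 0.01 * 100.0)

    def test_fractal_reduces_to_radial(self):
        # D = d−1 and a = d recovers surface-limited radial growth
        for d in (2, 3):
            frac = GrowthLawSpec("fractal", lam=0.2, delta=0.01, d=d,
                                 D=d - 1 + 1e-12, a=float(d))
            rad = GrowthLawSpec("radial", lam=0.2, delta=0.01, d=d)
            for n in (1.0, 10.0, 1e4):
                assert rhs(frac, n) == pytest.approx(rhs(rad, n), rel=1e-9)

    def test_fractal_dimension_range_enforced(self):
        with pytest.raises(ValueError):
            GrowthLawSpec("fractal", d=2, D=0.5)

    def test_exp_indicator_switches_off_at_saturation(self):
        spec = GrowthLawSpec("exp_indicator", lam=0.5, delta=0.0)
        assert rhs(spec, 0.999) == pytest.approx(0.5 * 0.999)
        assert rhs(spec, 1.0) == 0.0


class TestGompertzLimit:
    def test_gen_logistic_tends_to_gompertz_as_omega_shrinks(self):
        # λ(1 − u^ω) → −λω·ln u as ω → 0 with λω = C fixed
        C = 0.1
        u = np.linspace(0.01, 1.0, 200)
        sups = []
        for omega in (1.0, 0.1, 0.01):
            gl = GrowthLawSpec("gen_logistic", lam=C / omega, omega_bar=omega)
            go = GrowthLawSpec("gompertz", lam=C / omega, omega_bar=omega)
            sups.append(np.max(np.abs(rhs(gl, u) - rhs(go, u))))
        assert sups[0] > sups[1] > sups[2]
        assert sups[2] < 1e-3


class TestSolve:
    def test_exponential_closed_form(self):
        t = np.linspace(0, 50, 101)
        u = solve(GrowthLawSpec("exponential", lam=0.08, delta=0.0), 0.01, t)
        assert np.allclose(u, 0.01 * np.exp(0.08 * t), rtol=1e-8)

    def test_radial_quadratic_closed_form(self):
        # ṅ = 2λ√n separates to n(t) = (λt + √n0)²
        t = np.linspace(0, 100, 51)
        n = solve(GrowthLawSpec("radial", lam=0.1, delta=0.0, d=2), 4.0, t)
        assert np.allclose(n, (0.1 * t + 2.0) ** 2, rtol=1e-6)

    def test_gompertz_closed_form(self):
        t = np.linspace(0, 80, 81)
        spec = GrowthLawSpec("gompertz", lam=0.05, delta=0.0, omega_bar=2.0)
        u = solve(spec, 0.02, t)
        expected = np.exp(np.log(0.02) * np.exp(-0.05 * 2.0 * t))
        assert np.allclose(u, expected, rtol=1e-8)
        assert np.allclose(gompertz_solution(t, 0.02, 0.05, 2.0), expected,
                           rtol=1e-12)

    def test_genlogistic_solution_solves_the_ode(self):
        t = np.linspace(0, 120, 61)
        spec = GrowthLawSpec("gen_logistic", lam=0.1, delta=0.004, omega_bar=8.0)
        assert np.allclose(solve(spec, 0.01, t),
                           genlogistic_solution(t, 0.01, 0.1, 8.0, 0.004),
                           rtol=1e-7)

    def test_genlogistic_equal_rates_branch(self):
        t = np.linspace(0, 40, 21)
        spec = GrowthLawSpec("gen_logistic", lam=0.05, delta=0.05, omega_bar=3.0)
        assert np.allclose(solve(spec, 0.2, t),
                           genlogistic_solution(t, 0.2, 0.05, 3.0, 0.05),
                           rtol=1e-6)

    def test_genlogistic_converges_to_carrying_capacity(self):
        t = np.linspace(0, 2000, 101)
        for u0 in (0.001, 0.5, 0.99):
            u = solve(GrowthLawSpec("gen_logistic", lam=0.1, omega_bar=4.0), u0, t)
            assert u[-1] == pytest.approx(1.0, abs=1e-6)

    def test_density_laws_monotone_bounded(self):
        # first-order laws grow monotonically from any small density; the
        # second-order expansions are only growth laws inside their
        # validity region (near saturation), so start them there
        t = np.linspace(0, 500, 201)
        cases = [("gen_logistic", 0.05), ("gompertz", 0.05),
                 ("gen_logistic_2nd", 0.7), ("gompertz_2nd", 0.7)]
        for law, u0 in cases:
            spec = GrowthLawSpec(law, lam=0.1, delta=0.0, omega_bar=4.0,
                                 sigma_omega=0.5)
            u = solve(spec, u0, t)
            assert np.all(np.diff(u) >= -1e-9)
            assert u.max() <= 1.0 + 1e-7

    def test_exp_indicator_exactly_exponential_then_halts(self):
        t = np.linspace(0, 200, 401)
        u = solve(GrowthLawSpec("exp_indicator", lam=0.05, delta=0.0), 0.01, t)
        grow = u < 1.0
        assert np.allclose(u[grow], 0.01 * np.exp(0.05 * t[grow]), rtol=1e-10)
        assert u[-1] == 1.0
        # no pre-saturation slowdown, unlike the logistic family
        logistic = solve(GrowthLawSpec("gen_logistic", lam=0.05, omega_bar=1.0),
                         0.01, t)
        assert np.any(u[grow] > logistic[grow] * 1.05)

    def test_invalid_initial_conditions_rejected(self):
        with pytest.raises(ValueError):
            solve(GrowthLawSpec("gompertz", omega_bar=1.0), 0.0,
                  np.linspace(0, 1, 5))
        with pytest.raises(ValueError):
            solve(GrowthLawSpec("exponential"), np.nan, np.linspace(0, 1, 5))


class TestValidityConditions:
    def test_gompertz_condition_at_saturation(self):
        holds, margin = gompertz_condition(1.0, 0.0, 1.0)
        assert holds and margin > 1e20

    def test_gompertz_condition_small_density_fails(self):
        holds, margin = gompertz_condition(1.0, 0.0, np.exp(-20.0))
        assert not holds
        assert margin == pytest.approx(0.1)

    def test_genlogistic_condition_cases(self):
        assert genlogistic_condition(0.0, 0.37)[0]
        assert genlogistic_condition(1.0, 1.0)[0]
        holds, margin = genlogistic_condition(1.0, np.exp(-2.0))
        assert not holds and margin == pytest.approx(0.5)

    def test_condition_justifies_dropping_second_order_term(self):
        # wherever the margin is ≥ 10, the (ln u)² correction changes the
        # Gompertz rhs by under 10%
        for omega in (0.2, 0.5, 1.0, 2.0):
            for u in np.geomspace(1e-4, 0.999, 60):
                holds, _ = gompertz_condition(omega, 0.0, u)
                if not holds:
                    continue
                g1 = rhs(GrowthLawSpec("gompertz", lam=0.1, omega_bar=omega), u)
                g2 = rhs(GrowthLawSpec("gompertz_2nd", lam=0.1,
                                       omega_bar=omega), u)
                if abs(g1) > 1e-12:
                    assert abs(g2 - g1) / abs(g1) < 0.1

    def test_nonpositive_density_rejected(self):
        with pytest.raises(ValueError):
            gompertz_condition(1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            genlogistic_condition(1.0, -0.5)
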
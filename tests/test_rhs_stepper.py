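"""Right-hand-side structure and time-stepper correctness.

The compiled stepper is checked against (a) exact conservation identities
of the membrane-exchange terms, (b) an independent general-purpose stiff
integrator on the well-mixed (pure-ODE) limit, (c) the pure-numpy reference
right-hand side, and (d) its own refinement behaviour.
"""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from biofilmosc import run_1d, step_1d, rhs_1d
from biofilmosc.model1d import (FIELD_NAMES, VariantSpec,
                                make_initial_state, IntegrationError)


def _total(state, *names):
    w = state.grid.widths()
    return sum(float(np.sum(w * getattr(state, n))) for n in names)


class TestConservation:
    def test_closed_system_conserves_total_potassium(self, p):
        # membrane terms cancel exactly between the K and K_in equations
        st = make_initial_state(0.15, p, {"K": 12.0, "n": 0.4,
                                          "G_in": 8.0})
        st.K += np.linspace(0.0, 5.0, st.grid.n_nodes)   # non-uniform
        tot0 = _total(st, "K", "K_in")
        out = step_1d(st, p, t_span=1.0, closed=True, growth_off=True)
        assert _total(out, "K", "K_in") == pytest.approx(tot0, rel=1e-10)

    def test_closed_system_glutamate_lost_only_to_consumption(self, p):
        st = make_initial_state(0.15, p, {"G": 25.0, "G_in": 15.0})
        dt = 1e-5
        tot0 = _total(st, "G", "G_in")
        out = step_1d(st, p, t_span=dt, closed=True, growth_off=True)
        d = rhs_1d(st, p, closed=True, growth_off=True)
        w = st.grid.widths()
        consumed = float(np.sum(
            w * (d["G"] + d["G_in"] - (-p.gamma_G * st.G_in
                                       * (_mgrow_term(st, p) + p.r_b)))))
        # the only non-cancelling term in d(G+G_in)/dt is consumption
        assert consumed == pytest.approx(0.0, abs=1e-9)
        rate = (_total(out, "G", "G_in") - tot0) / dt
        expected = -float(np.sum(w * p.gamma_G * st.G_in
                                 * (_mgrow_term(st, p) + p.r_b)))
        assert rate == pytest.approx(expected, rel=1e-3)


def _mgrow_term(st, p):
    from biofilmosc.model1d import growth_mode
    return growth_mode(st.G_in, st.V, p)


class TestOdeLimitOracle:
    def test_well_mixed_limit_matches_stiff_integrator(self, p):
        """Uniform closed system with growth off is a 9-variable ODE; the
        stepper must agree with an off-the-shelf stiff integrator."""
        init = {"G": 30.0, "K": 8.0, "G_in": 20.0, "K_in": 300.0,
                "K_acclimated": 8.0, "V": -156.0, "n": 0.1}
        st = make_initial_state(0.1, p, init)

        def ode(t, y):
            G, K, Gin, Kin, Kacc, V, n, T, A = y
            sig = 1.0 / (1.0 + np.exp(V - p.V_th))
            upt = p.delta_G * sig * G * max(p.G_max - Gin, 0.0)
            V_K = p.V_K0 + p.delta_K * K
            V_L = p.V_L0 + p.delta_L * (K - Kacc)
            Jg = p.F * p.g_K * n**4 * (V - V_K)
            Jl = p.F * p.g_L * (V - V_L)
            Jp = max(p.gamma_K * K * (p.K_max - Kin), 0.0)
            TG = Gin / (Gin + p.G_u)
            TV = p.eta_V * (np.tanh(p.gamma_V * (V / p.V_low - 1.0)) + 1.0)
            M = TG / (TG + TV)
            c = max(p.G_max - Gin, 0.0)
            h = c**p.m / ((p.G_max - p.G_l) ** p.m + c**p.m)
            return [
                -upt,
                Jg + Jl - Jp,
                upt - p.gamma_G * Gin * (M + p.r_b),
                -Jg - Jl + Jp,
                p.eta_K * (K - Kacc),
                (-Jg - Jl - Jp) / p.F,
                p.alpha * h * (1.0 - n) - p.beta * n,
                p.alpha_T / (1.0 + np.exp(p.g_T * (V - p.V_0T)))
                - p.gamma_T * T,
                p.alpha_A * K - p.gamma_A * A,
            ]

        y0 = [init["G"], init["K"], init["G_in"], init["K_in"],
              init["K_acclimated"], init["V"], init["n"],
              float(st.T[0]), float(st.A[0])]
        sol = solve_ivp(ode, (0.0, 1.0), y0, method="Radau",
                        rtol=1e-10, atol=1e-10)
        ref = sol.y[:, -1]

        out = step_1d(st, p, t_span=1.0, closed=True, growth_off=True)
        got = np.array([getattr(out, a)[0] for a in
                        ("G", "K", "G_in", "K_in", "K_acclimated", "V",
                         "n", "T", "A")])
        scale = np.maximum(np.abs(ref), 1.0)
        assert np.max(np.abs(got - ref) / scale) < 1e-4


class TestKernelMatchesReferenceRhs:
    def test_one_small_step_equals_explicit_euler_of_rhs(self, p):
        st = make_initial_state(0.15, p, {"G": 25.0, "G_in": 15.0,
                                          "K": 10.0, "n": 0.3,
                                          "V": -170.0,
                                          "K_acclimated": 9.0})
        # break uniformity so advection and diffusion terms are non-trivial
        x = st.grid.x
        st.G *= 1.0 - 0.3 * (x / x[-1]) ** 2
        st.K += 2.0 * np.sin(3 * x / x[-1])
        st.G_in -= 4.0 * (x / x[-1])
        dt = 1e-8
        d = rhs_1d(st, p)
        out = step_1d(st, p, dt_max=dt, t_span=dt)
        for name in FIELD_NAMES:
            attr = name.replace("K_acclimated", "K_acclimated")
            num = (getattr(out, attr) - getattr(st, attr)) / dt
            scale = max(np.abs(d[name]).max(), 1.0)
            assert np.max(np.abs(num - d[name])) / scale < 1e-3, name

    def test_rhs_raises_on_non_finite_state(self, p):
        st = make_initial_state(0.15, p)
        st.V[3] = np.nan
        with pytest.raises(IntegrationError):
            rhs_1d(st, p)


class TestFixedPoint:
    def test_exact_equilibrium_is_stationary(self, p):
        """G=0, G_in=0, K=224 with V=V_K=V_L=-156 zeroes every derivative
        of the closed, non-growing system."""
        n_star = p.alpha * 0.8 / (p.alpha * 0.8 + p.beta)
        K_eq = (p.V_K0 - p.V_L0) / -1.0   # -380 + K = -156  =>  K = 224
        T_eq = p.alpha_T / ((1.0 + np.exp(p.g_T * (-156.0 - p.V_0T)))
                            * p.gamma_T)
        init = {"G": 0.0, "K": K_eq, "G_in": 0.0, "K_in": 300.0,
                "K_acclimated": K_eq, "V": -156.0, "n": n_star,
                "T": T_eq, "A": p.alpha_A * K_eq / p.gamma_A}
        st = make_initial_state(0.12, p, init)
        d = rhs_1d(st, p, closed=True, growth_off=True)
        for name in FIELD_NAMES:
            assert np.max(np.abs(d[name])) < 1e-9, name
        out = step_1d(st, p, t_span=0.5, closed=True, growth_off=True)
        for name in FIELD_NAMES:
            assert np.allclose(getattr(out, name), getattr(st, name),
                               atol=1e-7), name


class TestRefinement:
    def test_halved_resolution_changes_mean_v_below_one_percent(self, p):
        a = run_1d(0.150, p, 1.0, dx=0.002, dt_max=5e-4)
        b = run_1d(0.150, p, 1.0, dx=0.001, dt_max=2.5e-4)
        assert abs(a.mean_V_mV[-1] - b.mean_V_mV[-1]) \
            / abs(b.mean_V_mV[-1]) < 0.01

    def test_large_dt_matches_small_dt_through_substepping(self, p):
        a = run_1d(0.150, p, 1.0, dt_max=5e-4)
        b = run_1d(0.150, p, 1.0, dt_max=1e-4)
        assert abs(a.mean_V_mV[-1] - b.mean_V_mV[-1]) \
            / abs(b.mean_V_mV[-1]) < 0.01

    def test_zero_horizon_returns_single_initial_record(self, p):
        tr = run_1d(0.150, p, 0.0)
        assert len(tr) == 1
        assert tr.mean_V_mV[0] == pytest.approx(-156.0)
        assert tr.width_mm[0] == pytest.approx(0.150)


class TestVariantPlumbing:
    def test_constant_mgrow_suppresses_growth_modulation(self, p):
        v = VariantSpec(kind="constant_mgrow", mgrow_value=0.2)
        st = make_initial_state(0.2, p, {"G_in": 20.0, "V": -156.0})
        from biofilmosc.model1d import growth_velocity
        _, dLdt = growth_velocity(st, p, v)
        assert dLdt == pytest.approx(0.0075 * 20.0 * 0.2 * 0.2, rel=1e-6)

    def test_no_acclimation_overrides_delta_L(self, p):
        v = VariantSpec(kind="no_acclimation")
        assert v.apply_to_params(p).delta_L == pytest.approx(6.0)
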
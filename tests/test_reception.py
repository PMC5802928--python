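import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from mcchannel import (
    SystemParameters,
    association_solution,
    binding_ode_rhs,
    derive_transport,
    dissociation_solution,
    modified_params,
    received_signal,
    surface_concentration,
)


def integrate_binding_ode(params, c0, k_T, n_r0, t_eval):
    """Independent adaptive-RK oracle for the transport-limited Langmuir ODE."""
    sol = solve_ivp(
        lambda t, y: binding_ode_rhs(y[0], c0, params, k_T),
        (0.0, t_eval[-1]),
        [n_r0],
        t_eval=t_eval,
        method="RK45",
        rtol=1e-10,
        atol=1e-12 * max(params.N_R_max, 1e-300),
    )
    assert sol.success
    return sol.y[0]


class TestSurfaceConcentration:
    def test_transport_unlimited_limit(self, default_params):
        c = surface_concentration(1e-3, 0.0, default_params, k_T=1.0)
        assert c == pytest.approx(1e-3, rel=1e-8)

    def test_zero_everything(self, default_params):
        assert surface_concentration(0.0, 0.0, default_params, 1e-16) == 0.0

    def test_bare_receiver_partition(self, default_params, derived):
        p = default_params
        c = surface_concentration(1e-3, 0.0, p, derived.k_T)
        expected = derived.k_T * 1e-3 / (p.k1 * p.N_R_max + derived.k_T)
        assert c == pytest.approx(expected, rel=1e-12)

    def test_overfull_receiver_rejected(self, default_params):
        with pytest.raises(ValueError):
            surface_concentration(1e-3, 2 * default_params.N_R_max, default_params, 1e-16)


class TestBindingOdeRhs:
    def test_equilibrium_is_fixed_point(self, default_params, derived):
        p = default_params
        c0 = 1e-3
        n_eq = p.N_R_max * c0 / (c0 + p.K_D)
        assert binding_ode_rhs(n_eq, c0, p, derived.k_T) == pytest.approx(
            0.0, abs=1e-30
        )

    def test_well_mixed_limit(self, default_params):
        p = default_params
        c0, n_r = 1e-3, 1e-18
        rhs = binding_ode_rhs(n_r, c0, p, k_T=1.0)
        langmuir = p.k1 * c0 * (p.N_R_max - n_r) - p.k_minus1 * n_r
        assert rhs == pytest.approx(langmuir, rel=1e-6)

    def test_pure_dissociation_is_negative(self, default_params, derived):
        assert binding_ode_rhs(1e-18, 0.0, default_params, derived.k_T) < 0


class TestClosedFormsAgainstOdeOracle:
    def test_association_boundary_values(self, tc):
        assert association_solution(0.0, tc) == 0.0
        assert association_solution(1e9, tc) == pytest.approx(
            tc.N_R_eq_star, rel=1e-9
        )

    def test_dissociation_boundary_values(self, tc):
        tc_d = tc.with_initial(0.5 * tc.N_R_max)
        assert dissociation_solution(0.0, tc_d) == pytest.approx(
            tc_d.N_R_0, rel=1e-12
        )
        assert dissociation_solution(1e9, tc_d) == pytest.approx(0.0, abs=1e-40)

    def test_association_matches_rk_default(self, default_params, derived, plug, tc):
        t = np.linspace(0.0, 3 * plug.tau_p_rect, 400)
        closed = association_solution(t, tc)
        oracle = integrate_binding_ode(
            default_params, plug.c_avg, derived.k_T_star, 0.0, t
        )
        np.testing.assert_allclose(closed, oracle, rtol=0, atol=1e-6 * tc.N_R_eq_star)

    def test_dissociation_matches_rk_default(self, default_params, derived, tc):
        n_r0 = 0.5 * default_params.N_R_max
        tc_d = tc.with_initial(n_r0)
        t = np.linspace(0.0, 600.0, 400)
        closed = dissociation_solution(t, tc_d)
        oracle = integrate_binding_ode(default_params, 0.0, derived.k_T_star, n_r0, t)
        np.testing.assert_allclose(closed, oracle, rtol=0, atol=1e-6 * n_r0)

    def test_well_mixed_limit_is_textbook_langmuir(self, default_params, plug):
        # k_T* -> inf: association converges to N_eq (1 - exp(-(k1 c + k-1) t))
        p = default_params
        c = plug.c_avg
        tc_inf = modified_params(c, p, k_T_star=1.0)  # >> k1*N_R_max = 4e-16
        t = np.linspace(0.0, 60.0, 200)
        closed = association_solution(t, tc_inf)
        n_eq = p.N_R_max * c / (c + p.K_D)
        langmuir = n_eq * (1.0 - np.exp(-(p.k1 * c + p.k_minus1) * t))
        np.testing.assert_allclose(closed, langmuir, rtol=0, atol=1e-6 * n_eq)


class TestModifiedParams:
    def test_saturation(self, default_params, derived):
        tc = modified_params(1e3 * default_params.K_D, default_params, derived.k_T_star)
        assert tc.N_R_eq_star == pytest.approx(default_params.N_R_max, rel=2e-3)

    def test_half_saturation_at_kd(self, default_params, derived):
        tc = modified_params(default_params.K_D, default_params, derived.k_T_star)
        assert tc.N_R_eq_star == pytest.approx(default_params.N_R_max / 2, rel=1e-12)

    def test_well_mixed_observed_rate(self, default_params):
        c = 1e-3
        tc = modified_params(c, default_params, k_T_star=1.0)
        assert tc.beta_star == pytest.approx(
            default_params.k1 * c + default_params.k_minus1, rel=1e-6
        )

    def test_gamma_bounds_initial_condition(self, tc, default_params):
        assert tc.gamma_star >= default_params.N_R_max
        with pytest.raises(ValueError):
            tc.with_initial(2 * tc.gamma_star)


class TestReceivedSignal:
    def test_zero_before_association(self, default_params, derived, plug, default_time_grid):
        sig = received_signal(default_time_grid, default_params, derived, plug)
        assert np.all(sig.N_R[default_time_grid < plug.t_a] == 0.0)

    def test_continuous_at_dissociation_start(self, default_params, derived, plug):
        eps = 1e-9
        t = np.array([0.0, plug.t_d - eps, plug.t_d, plug.t_d + eps])
        sig = received_signal(t, default_params, derived, plug)
        assert sig.N_R[2] == pytest.approx(sig.N_R[1], rel=1e-6)
        assert sig.N_R[3] == pytest.approx(sig.N_R[2], rel=1e-6)

    def test_monotone_rise_then_decay(self, default_params, derived, plug, default_time_grid):
        sig = received_signal(default_time_grid, default_params, derived, plug)
        t = default_time_grid
        rise = sig.N_R[(t >= plug.t_a) & (t < plug.t_d)]
        decay = sig.N_R[t >= plug.t_d]
        assert np.all(np.diff(rise) > 0)
        assert np.all(np.diff(decay) < 0)

    def test_bounded_by_equilibrium(self, default_params, derived, plug, tc, default_time_grid):
        sig = received_signal(default_time_grid, default_params, derived, plug, tc=tc)
        assert np.all(sig.N_R >= 0.0)
        assert np.all(sig.N_R <= min(tc.N_R_eq_star, default_params.N_R_max) * (1 + 1e-12))

    def test_truncated_grid_warns(self, default_params, derived, plug, caplog):
        t = np.linspace(0.0, plug.t_a, 50)  # ends before dissociation
        with caplog.at_level("WARNING", logger="mcchannel.reception"):
            received_signal(t, default_params, derived, plug)
        assert any("truncated" in rec.message for rec in caplog.records)

    def test_bad_grids_rejected(self, default_params, derived, plug):
        with pytest.raises(ValueError):
            received_signal(np.array([0.0, 0.0, 1.0]), default_params, derived, plug)
        with pytest.raises(ValueError):
            received_signal(np.array([-1.0, 1.0]), default_params, derived, plug)


@given(
    log_c=st.floats(-2, 2),
    log_k1=st.floats(-1.5, 1.5),
    log_km1=st.floats(-1.5, 1.5),
)
def test_association_monotone_and_bounded_property(log_c, log_km1, log_k1):
    """Association curves are increasing and bounded by N_eq for any kinetics."""
    base = SystemParameters()
    p = base.replace(k1=base.k1 * 10**log_k1, k_minus1=base.k_minus1 * 10**log_km1)
    derived = derive_transport(p)
    c = 1.4e-3 * 10**log_c
    tc = modified_params(c, p, derived.k_T_star)
    t = np.linspace(0.0, 200.0, 101)
    n = association_solution(t, tc)
    assert np.all(np.diff(n) >= -1e-25)
    assert np.all(n <= tc.N_R_eq_star * (1 + 1e-10))
    assert n[0] == 0.0
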
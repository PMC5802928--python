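import numpy as np
import pytest
from scipy import integrate

from mcchannel import (
    N_A,
    SystemParameters,
    derive_transport,
    effective_plug_concentration,
    impulse_response_at_receiver,
    plug_descriptor,
    rect_response_at_receiver,
    tx_rx_distance,
)


class TestTxRxDistance:
    @pytest.mark.parametrize(
        "d_rx,l_rx,expected",
        [(15e-3, 20e-6, 1.501e-2), (0.7, 0.0, 0.7), (0.0, 2.0, 1.0)],
    )
    def test_center_of_receiver(self, d_rx, l_rx, expected):
        assert tx_rx_distance(d_rx, l_rx) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            tx_rx_distance(-1.0, 1.0)


class TestImpulseResponse:
    def test_peak_value_at_transit_time(self, default_params, derived):
        # 1/sqrt(4 pi D d / u) evaluated directly with the default numbers
        t_peak = derived.d / default_params.u
        peak = impulse_response_at_receiver(t_peak, default_params, derived)
        expected = 1.0 / np.sqrt(4 * np.pi * derived.D * derived.d / default_params.u)
        assert peak == pytest.approx(expected, rel=1e-12)
        assert peak == pytest.approx(1175.03, rel=1e-4)

    def test_symmetric_about_peak(self, default_params, derived):
        t_peak = derived.d / default_params.u
        for delta in (1.0, 5.0, 20.0):
            assert impulse_response_at_receiver(
                t_peak - delta, default_params, derived
            ) == pytest.approx(
                impulse_response_at_receiver(t_peak + delta, default_params, derived),
                rel=1e-12,
            )

    def test_nonpositive_time_rejected(self, default_params, derived):
        with pytest.raises(ValueError):
            impulse_response_at_receiver(0.0, default_params, derived)


class TestRectResponse:
    def test_zero_at_origin(self, default_params, derived):
        assert rect_response_at_receiver(0.0, default_params, derived) == pytest.approx(
            0.0, abs=1e-30
        )

    def test_mass_conservation(self, default_params, derived):
        # time integral equals mu_T T_p/(u A_ch N_A): every released molecule
        # eventually sweeps past the receiver in the 1-D transport picture
        p = default_params
        total, err = integrate.quad(
            lambda t: rect_response_at_receiver(t, p, derived), 0, 1000, limit=500
        )
        expected = p.mu_T * p.T_p / (p.u * derived.A_ch * N_A)
        assert total == pytest.approx(expected, rel=1e-7)

    def test_peak_near_plug_delay(self, default_params, derived, plug):
        # value at t_D within 1% of the curve maximum (numerical maximisation)
        from scipy.optimize import minimize_scalar

        p = default_params
        res = minimize_scalar(
            lambda t: -rect_response_at_receiver(t, p, derived),
            bounds=(plug.t_a, plug.t_d),
            method="bounded",
        )
        peak = -res.fun
        at_t_d = rect_response_at_receiver(plug.t_D, p, derived)
        assert at_t_d == pytest.approx(peak, rel=1e-2)

    def test_linear_in_transmission_rate(self, default_params, derived):
        p2 = default_params.replace(mu_T=2 * default_params.mu_T)
        d2 = derive_transport(p2)
        t = np.linspace(280.0, 340.0, 7)
        np.testing.assert_allclose(
            rect_response_at_receiver(t, p2, d2),
            2 * rect_response_at_receiver(t, default_params, derived),
            rtol=1e-12,
        )


class TestPlugDescriptor:
    def test_reference_values(self, plug):
        # direct arithmetic with the default operating point
        assert plug.sigma_R == pytest.approx(3.39517e-4, rel=1e-5)
        assert plug.t_D == pytest.approx(300.45, rel=1e-10)
        assert plug.tau_p_rect == pytest.approx(27.6613, rel=1e-5)
        assert plug.t_a == pytest.approx(286.6193, rel=1e-5)
        assert plug.t_d == pytest.approx(314.2807, rel=1e-5)

    def test_window_centred_on_plug_delay(self, plug):
        assert plug.t_a == pytest.approx(plug.t_D - plug.tau_p_rect / 2)
        assert plug.t_d == pytest.approx(plug.t_D + plug.tau_p_rect / 2)
        assert plug.t_a < plug.t_D < plug.t_d

    def test_no_dispersion_limit(self):
        # with negligible dispersion the plug duration approaches the
        # transmitted pulse length (sigma_R -> 0 limit)
        p = SystemParameters(
            h_ch=1e-7, w_ch=1e-7, d_rx=1e-3, l_rx=1e-6, u=1e-3, T_p=5.0
        )
        d = derive_transport(p)
        assert d.D == pytest.approx(p.D0, rel=1e-2)  # dispersion suppressed
        plug = plug_descriptor(p, d)
        assert plug.tau_p_rect == pytest.approx(p.T_p, rel=2e-2)

    def test_four_sigma_window_covers_95_percent(self, default_params, derived):
        # fraction of the frozen-variance Gaussian inside the 4 sigma window;
        # equals 2*Phi(2)-1 = 95.45%, inside the expected 95-96% band
        from scipy.stats import norm

        p = default_params
        u = p.u
        t_c = derived.d / u
        half = 2.0 * np.sqrt(2.0 * derived.D * derived.d / u) / u  # 2 sigma in time
        mass, _ = integrate.quad(
            lambda t: impulse_response_at_receiver(t, p, derived) * u,
            t_c - half,
            t_c + half,
        )
        assert 0.95 <= mass <= 0.96
        assert mass == pytest.approx(2 * norm.cdf(2) - 1, rel=1e-9)


class TestEffectivePlugConcentration:
    def test_reference_value_matches_trapezoid_oracle(
        self, default_params, derived, plug
    ):
        # independent fixed-grid trapezoid integration of the receiver
        # concentration over the plug window
        t = np.linspace(plug.t_a, plug.t_d, 200001)
        oracle = np.trapezoid(
            rect_response_at_receiver(t, default_params, derived), t
        ) / (plug.t_d - plug.t_a)
        assert plug.c_avg == pytest.approx(oracle, rel=1e-9)
        assert plug.c_avg == pytest.approx(1.4382e-3, rel=1e-4)

    def test_linear_in_transmission_rate(self, default_params, plug):
        p2 = default_params.replace(mu_T=2 * default_params.mu_T)
        plug2 = plug_descriptor(p2, derive_transport(p2))
        assert plug2.c_avg == pytest.approx(2 * plug.c_avg, rel=1e-9)

    def test_mean_below_max(self, default_params, derived, plug):
        t = np.linspace(plug.t_a, plug.t_d, 2001)
        assert plug.c_avg <= rect_response_at_receiver(
            t, default_params, derived
        ).max()

    def test_bad_window_rejected(self, default_params, derived):
        with pytest.raises(ValueError):
            effective_plug_concentration(default_params, derived, 10.0, 10.0)
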
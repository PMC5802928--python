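"""Analytical convection-diffusion propagation and the effective-plug construction.

Ignoring the surface reaction, the channel acts as a linear time-invariant
1-D dispersion line: an impulse released at the inlet arrives at the receiver
as a Gaussian concentration plug travelling at the peak flow velocity ``u``
with frozen variance ``sigma_R^2 = 2 D d / u`` (the dispersion accumulated
over the transit, pinned at the receiver location so the subsequent receptor
kinetics stay tractable).  A rectangular transmit pulse gives the difference
of two error functions.

For the receptor model the passing plug is then collapsed into an *effective
rectangular plug*: a window ``[t_a, t_d]`` centred on the plug delay ``t_D``,
wide enough (4 sigma plus the pulse length) to cover ~95% of the transmitted
ligands, carrying the time-averaged concentration ``c_avg`` seen at the
receiver during the window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.special import erf

from .params import N_A, DerivedTransport, SystemParameters


def tx_rx_distance(d_rx: float, l_rx: float) -> float:
    """Transmitter-receiver distance: inlet to the center of the receiver (m)."""
    if d_rx < 0 or l_rx < 0:
        raise ValueError("d_rx and l_rx must be non-negative")
    return d_rx + l_rx / 2.0


def impulse_response_at_receiver(
    t: float | np.ndarray, params: SystemParameters, derived: DerivedTransport
) -> float | np.ndarray:
    """Channel impulse response at the receiver (1/m) per unit surface release.

    Frozen-variance Gaussian ``(4 pi D d / u)^{-1/2} exp(-(d - u t)^2 / (4 D d / u))``
    for a release of one mol/m^2 of inlet cross-section.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("impulse response defined for t > 0 only")
    var2 = 4.0 * derived.D * derived.d / params.u  # = 2 sigma_R^2
    out = np.exp(-((derived.d - params.u * t) ** 2) / var2) / np.sqrt(np.pi * var2)
    return float(out) if out.ndim == 0 else out


def rect_response_at_receiver(
    t: float | np.ndarray, params: SystemParameters, derived: DerivedTransport
) -> float | np.ndarray:
    """Concentration at the receiver for a rectangular transmit pulse (mol/m^3).

    Convolution of the impulse response with a pulse releasing ``mu_T``
    molecules/s for ``T_p`` seconds spread over the inlet cross-section::

        c(t) = mu_T / (2 u A_ch N_A) * [erf((u t - d)/(2 sqrt(D d/u)))
                                        - erf((u t - u T_p - d)/(2 sqrt(D d/u)))]

    Non-negative for all t; its time integral equals mu_T T_p / (u A_ch N_A)
    (all released molecules eventually sweep past the receiver).
    """
    t = np.asarray(t, dtype=float)
    scale = 2.0 * np.sqrt(derived.D * derived.d / params.u)
    amp = params.mu_T / (2.0 * params.u * derived.A_ch * N_A)
    out = amp * (
        erf((params.u * t - derived.d) / scale)
        - erf((params.u * t - params.u * params.T_p - derived.d) / scale)
    )
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PlugDescriptor:
    """Effective rectangular plug seen by the receiver.

    Attributes
    ----------
    sigma_R : float
        Plug standard deviation at the receiver location (m).
    t_D : float
        Plug delay: passage of the peak concentration through the receiver
        center, ``d/u + T_p/2`` (s).
    w_p_rect : float
        Effective plug length ``4 sigma_R + T_p u`` (m), covering ~95-96%
        of the transmitted ligands.
    tau_p_rect : float
        Effective plug passage duration ``w_p_rect / u`` (s).
    t_a, t_d : float
        Association and dissociation start times, ``t_D -+ tau_p_rect/2`` (s).
    c_avg : float
        Effective plug concentration: time-average of the receiver
        concentration over ``[t_a, t_d]`` (mol/m^3).
    """

    sigma_R: float
    t_D: float
    w_p_rect: float
    tau_p_rect: float
    t_a: float
    t_d: float
    c_avg: float


def effective_plug_concentration(
    params: SystemParameters,
    derived: DerivedTransport,
    t_a: float,
    t_d: float,
    rtol: float = 1e-10,
) -> float:
    """Time-averaged receiver concentration over the plug window (mol/m^3).

    Adaptive quadrature of the rectangular-pulse response over ``[t_a, t_d]``
    divided by the window length.  Quadrature non-convergence raises.
    """
    if not t_a < t_d:
        raise ValueError("require t_a < t_d")
    value, abserr = integrate.quad(
        lambda t: rect_response_at_receiver(t, params, derived),
        t_a,
        t_d,
        epsrel=rtol,
        epsabs=0.0,
        limit=200,
    )
    if value <= 0:
        raise ValueError("effective plug concentration must be positive")
    if abserr > 1e-6 * value:
        raise RuntimeError(
            f"plug-concentration quadrature did not converge: value={value}, abserr={abserr}"
        )
    return value / (t_d - t_a)


def plug_descriptor(
    params: SystemParameters, derived: DerivedTransport
) -> PlugDescriptor:
    """Construct the effective rectangular plug for a parameter set."""
    sigma_R = np.sqrt(2.0 * derived.D * derived.d / params.u)
    t_D = derived.d / params.u + params.T_p / 2.0
    w_p_rect = 4.0 * sigma_R + params.T_p * params.u
    tau_p_rect = w_p_rect / params.u
    t_a = t_D - tau_p_rect / 2.0
    t_d = t_D + tau_p_rect / 2.0
    c_avg = effective_plug_concentration(params, derived, t_a, t_d)
    return PlugDescriptor(
        sigma_R=float(sigma_R),
        t_D=float(t_D),
        w_p_rect=float(w_p_rect),
        tau_p_rect=float(tau_p_rect),
        t_a=float(t_a),
        t_d=float(t_d),
        c_avg=float(c_avg),
    )
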
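"""Closed-form received-pulse characteristics: delay, amplitude, width.

These are the channel metrics a communication engineer reads off the
received signal: when the bound-receptor pulse peaks (delay), how high it
gets (amplitude), and how long it stays above half its peak (width, the
quantity that controls intersymbol interference).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from .params import DerivedTransport, SystemParameters
from .reception import TwoCompartmentParams, association_solution
from .transport import PlugDescriptor


@dataclass(frozen=True)
class PulseMetrics:
    """Received-pulse characteristics.

    ``t_pd``: pulse delay, time of the bound-receptor peak (s) — coincides
    with the plug exit time ``t_d`` because the signal rises while ligand is
    present and decays afterwards.  ``N_R_pa``: pulse amplitude (mol) and its
    normalised value ``N_R_pa / N_R_max``.  ``tau_pw``: full width at half
    maximum of the received pulse (s).
    """

    t_pd: float
    N_R_pa: float
    N_R_pa_norm: float
    tau_pw: float

    def to_json(self, inputs: dict | None = None) -> str:
        payload = {
            "t_pd_s": self.t_pd,
            "NR_pa_mol": self.N_R_pa,
            "NR_pa_normalized": self.N_R_pa_norm,
            "tau_pw_s": self.tau_pw,
        }
        if inputs is not None:
            payload["inputs"] = inputs
        return json.dumps(payload, indent=2)


def pulse_delay(params: SystemParameters, derived: DerivedTransport) -> float:
    """Pulse delay (s): ``t_pd = (d/u)(1 + sqrt(8 D/(u d))) + T_p``.

    Algebraically equal to the plug exit time ``t_d = t_D + tau_p_rect/2``.
    """
    d, u = derived.d, params.u
    return (d / u) * (1.0 + math.sqrt(8.0 * derived.D / (u * d))) + params.T_p


def pulse_amplitude(plug: PlugDescriptor, tc: TwoCompartmentParams) -> float:
    """Pulse amplitude (mol): the association value at the plug exit.

    The received signal is monotone increasing while the plug covers the
    receiver and monotone decreasing afterwards, so the peak is
    ``N_R(t_pd) = association_solution(t_d - t_a)``.
    """
    return float(association_solution(plug.t_d - plug.t_a, tc))


def pulse_width(
    plug: PlugDescriptor, tc: TwoCompartmentParams, N_R_pa: float
) -> float:
    """Full width at half maximum of the received pulse (s).

    Derived from the implicit (separable) solutions of the binding ODE.  With
    ``r = N_R_pa / (2 N_R_eq*)``, the rising half-max crossing sits
    ``(1/beta*)(alpha* r - ln(1 - r))`` after ``t_a`` and the falling
    crossing ``-(k1 (gamma* ln(1/2) + N_R_pa/2))/(k_T* k_minus1)`` after
    ``t_d``, giving::

        tau_pw = tau_p_rect - (1/beta*)(alpha* r - ln(1 - r))
                 - (k1 gamma* (ln(1/2) - N_R_pa/(2 gamma*)) + k1 N_R_pa)
                   / (k_T* k_minus1)
    """
    if N_R_pa <= 0:
        raise ValueError("pulse amplitude must be positive")
    r = N_R_pa / (2.0 * tc.N_R_eq_star)
    if r >= 1.0:
        raise ValueError(
            "N_R_pa exceeds 2*N_R_eq_star; invalid two-compartment parameters"
        )
    rise = (tc.alpha_star * r - math.log1p(-r)) / tc.beta_star
    fall = (
        tc.k1 * tc.gamma_star * (math.log(0.5) - N_R_pa / (2.0 * tc.gamma_star))
        + tc.k1 * N_R_pa
    ) / (tc.k_T_star * tc.k_minus1)
    return plug.tau_p_rect - rise - fall


def pulse_metrics(
    params: SystemParameters,
    derived: DerivedTransport,
    plug: PlugDescriptor,
    tc: TwoCompartmentParams,
) -> PulseMetrics:
    """Compute all three closed-form pulse characteristics."""
    t_pd = pulse_delay(params, derived)
    n_pa = pulse_amplitude(plug, tc)
    return PulseMetrics(
        t_pd=t_pd,
        N_R_pa=n_pa,
        N_R_pa_norm=n_pa / params.N_R_max,
        tau_pw=pulse_width(plug, tc, n_pa),
    )


def width_by_bisection(
    time: np.ndarray, values: np.ndarray
) -> float:
    """Half-maximum width of a sampled unimodal pulse (s), by interpolation.

    Locates the two half-maximum crossings bracketing the peak with linear
    interpolation between grid points.  Used as the independent cross-check
    of the closed-form width and to measure widths of numerical signals.
    """
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    i_peak = int(np.argmax(values))
    half = values[i_peak] / 2.0
    if values[i_peak] <= 0:
        raise ValueError("pulse has no positive peak")

    def _cross(i0: int, i1: int) -> float:
        # linear interpolation of the half-max crossing in [i0, i1]
        v0, v1 = values[i0], values[i1]
        if v1 == v0:
            return time[i0]
        frac = (half - v0) / (v1 - v0)
        return time[i0] + frac * (time[i1] - time[i0])

    below_left = np.nonzero(values[: i_peak + 1] < half)[0]
    if below_left.size == 0:
        raise ValueError("no rising half-max crossing in the sampled window")
    i = below_left[-1]
    t_rise = _cross(i, i + 1)

    below_right = np.nonzero(values[i_peak:] < half)[0]
    if below_right.size == 0:
        raise ValueError("no falling half-max crossing in the sampled window")
    j = i_peak + below_right[0]
    t_fall = _cross(j - 1, j)
    return float(t_fall - t_rise)
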
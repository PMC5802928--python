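"""Two-compartment ligand-receptor kinetics and the received-signal model.

The receiver is a patch of ``N_R_max`` receptors (in mol) on the channel
floor.  Transport to the surface is summarised by the volumetric parameter
``k_T`` (m^3/s): the bulk compartment holds the inlet concentration ``c0``
while the surface compartment concentration ``c|_{y=0}`` follows from
balancing the transport flux ``k_T (c0 - c|_{y=0})`` against the Langmuir
reactive flux.  Eliminating the surface concentration gives a single
nonlinear ODE for the bound amount ``N_R(t)``::

    dN_R/dt = (k1 k_T c0 (N_R_max - N_R) - k_minus1 k_T N_R)
              / (k1 (N_R_max - N_R) + k_T)

whose association (constant c0, N_R(0) = 0) and dissociation (c0 = 0,
N_R(0) = N_R_0) phases admit closed forms in the principal Lambert-W branch.
The received signal stitches the two phases at the plug window edges
``t_a`` / ``t_d`` with the effective plug concentration ``c_avg`` standing in
for c0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import lambertw, wrightomega

from .params import DerivedTransport, SystemParameters
from .transport import PlugDescriptor

logger = logging.getLogger(__name__)

_W_ARG_MIN = -1.0 / np.e + 1e-15


def surface_concentration(
    c0: float, N_R: float, params: SystemParameters, k_T: float
) -> float:
    """Quasi-steady ligand concentration at the receiver surface (mol/m^3).

    ``c|_{y=0} = (k_T c0 + k_minus1 N_R) / (k1 (N_R_max - N_R) + k_T)``;
    approaches ``c0`` in the transport-unlimited limit ``k_T -> inf``.
    """
    n_max = params.N_R_max
    if not 0.0 <= N_R <= n_max * (1 + 1e-12):
        raise ValueError(f"N_R must lie in [0, N_R_max={n_max}], got {N_R}")
    return (k_T * c0 + params.k_minus1 * N_R) / (
        params.k1 * (n_max - N_R) + k_T
    )


def binding_ode_rhs(
    N_R: float, c0: float, params: SystemParameters, k_T: float
) -> float:
    """Right-hand side of the transport-limited Langmuir ODE (mol/s)."""
    n_max = params.N_R_max
    return (
        params.k1 * k_T * c0 * (n_max - N_R) - params.k_minus1 * k_T * N_R
    ) / (params.k1 * (n_max - N_R) + k_T)


@dataclass(frozen=True)
class TwoCompartmentParams:
    """Coefficients of the closed-form bound-receptor solutions.

    All starred quantities absorb the calibrated transport parameter
    ``k_T_star`` and the effective plug concentration ``c_avg``:

    - ``N_R_eq_star`` (mol): equilibrium bound amount at c_avg,
    - ``alpha_star`` (dimensionless) and ``beta_star`` (1/s): shape and rate
      of the association transient,
    - ``gamma_star`` (mol): ``(k1 N_R_max + k_T_star)/k1``, the dissociation
      scale (always >= N_R_max),
    - ``N_R_0`` (mol): bound amount at the start of the dissociation phase.
    """

    N_R_eq_star: float
    alpha_star: float
    beta_star: float
    gamma_star: float
    k_T_star: float
    c_avg: float
    N_R_max: float
    k1: float
    k_minus1: float
    N_R_0: float = 0.0

    def with_initial(self, N_R_0: float) -> "TwoCompartmentParams":
        if not 0.0 <= N_R_0 <= self.gamma_star:
            raise ValueError("N_R_0 must lie in [0, gamma_star]")
        return TwoCompartmentParams(
            **{**self.__dict__, "N_R_0": float(N_R_0)}
        )


def modified_params(
    c_avg: float, params: SystemParameters, k_T_star: float
) -> TwoCompartmentParams:
    """Two-compartment coefficients for plug concentration ``c_avg``.

    ``N_R_eq* = c_avg/(c_avg+K_D) N_R_max``;
    ``alpha* = k1 c_avg N_R_max / (k_minus1 N_R_max + k_T*(c_avg+K_D))``;
    ``beta* = (k1 c_avg + k_minus1) / (1 + k_minus1 N_R_max/(k_T*(c_avg+K_D)))``;
    ``gamma* = (k1 N_R_max + k_T*)/k1``.
    """
    if c_avg <= 0:
        raise ValueError("c_avg must be positive")
    k1, km1 = params.k1, params.k_minus1
    n_max, K_D = params.N_R_max, params.K_D
    denom = km1 * n_max + k_T_star * (c_avg + K_D)
    return TwoCompartmentParams(
        N_R_eq_star=c_avg / (c_avg + K_D) * n_max,
        alpha_star=k1 * c_avg * n_max / denom,
        beta_star=(k1 * c_avg + km1)
        / (1.0 + km1 * n_max / (k_T_star * (c_avg + K_D))),
        gamma_star=(k1 * n_max + k_T_star) / k1,
        k_T_star=k_T_star,
        c_avg=c_avg,
        N_R_max=n_max,
        k1=k1,
        k_minus1=km1,
    )


def association_solution(
    t_rel: float | np.ndarray, tc: TwoCompartmentParams
) -> float | np.ndarray:
    """Bound amount during association, ``t_rel`` seconds after plug arrival (mol).

    ``N_R(t) = N_R_eq* (1 - W0(alpha* exp(alpha* - beta* t)) / alpha*)``.

    Evaluated as ``wrightomega(log alpha* + alpha* - beta* t)``, the exact
    principal-branch value without overflow for large ``alpha*``.  Satisfies
    N_R(0) = 0 (since W0(a e^a) = a) and N_R(inf) = N_R_eq*.
    """
    t_rel = np.asarray(t_rel, dtype=float)
    if np.any(t_rel < 0):
        raise ValueError("t_rel must be non-negative")
    a, b = tc.alpha_star, tc.beta_star
    w = wrightomega(np.log(a) + a - b * t_rel).real
    out = tc.N_R_eq_star * (1.0 - w / a)
    # exact boundary values despite rounding in the special function
    out = np.where(t_rel == 0.0, 0.0, np.maximum(out, 0.0))
    return float(out) if out.ndim == 0 else out


def dissociation_solution(
    t_rel: float | np.ndarray, tc: TwoCompartmentParams
) -> float | np.ndarray:
    """Bound amount during dissociation, ``t_rel`` seconds after plug exit (mol).

    ``N_R(t) = -gamma* W0(-(N_R_0/gamma*) exp(-N_R_0/gamma*
    - k_T* k_minus1 t / (k1 gamma*)))``; N_R(0) = N_R_0 (via
    W0(-x e^{-x}) = -x for x <= 1) and N_R(inf) = 0.
    """
    t_rel = np.asarray(t_rel, dtype=float)
    if np.any(t_rel < 0):
        raise ValueError("t_rel must be non-negative")
    g = tc.gamma_star
    x0 = tc.N_R_0 / g
    if x0 > 1.0:
        raise ValueError("N_R_0 exceeds gamma_star; invalid parameters")
    rate = tc.k_T_star * tc.k_minus1 / (tc.k1 * g)
    arg = -x0 * np.exp(-x0 - rate * t_rel)
    if np.any(arg < _W_ARG_MIN):
        logger.warning("Lambert-W argument clamped to -1/e (floating-point underflow)")
        arg = np.maximum(arg, _W_ARG_MIN)
    w = lambertw(arg, k=0).real
    out = -g * w
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ReceivedSignal:
    """Time course of the bound-receptor amount at the receiver.

    ``time`` (s), ``N_R`` (mol), ``N_R_normalized = N_R / N_R_max``
    (dimensionless) and a ``source`` tag, ``"analytical"`` for the
    closed-form model or ``"numerical"`` for the finite-difference solver.
    """

    time: np.ndarray
    N_R: np.ndarray
    N_R_max: float
    source: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "N_R", np.asarray(self.N_R, dtype=float))
        if self.time.shape != self.N_R.shape:
            raise ValueError("time and N_R must have the same shape")
        if self.source not in ("analytical", "numerical"):
            raise ValueError(f"unknown source tag {self.source!r}")

    @property
    def N_R_normalized(self) -> np.ndarray:
        return self.N_R / self.N_R_max


def received_signal(
    time: np.ndarray,
    params: SystemParameters,
    derived: DerivedTransport,
    plug: PlugDescriptor,
    tc: TwoCompartmentParams | None = None,
) -> ReceivedSignal:
    """Analytical received signal N_R(t) on a monotone time grid.

    Zero before ``t_a``; the association closed form on ``[t_a, t_d)``; the
    dissociation closed form from ``t_d`` on, started from the association
    value at ``t_d`` so the curve is continuous.
    """
    time = np.asarray(time, dtype=float)
    if time.ndim != 1 or time.size < 2:
        raise ValueError("time grid must be a 1-D array with >= 2 points")
    if np.any(np.diff(time) <= 0):
        raise ValueError("time grid must be strictly increasing")
    if time[0] < 0:
        raise ValueError("time grid must start at t >= 0")
    if tc is None:
        tc = modified_params(plug.c_avg, params, derived.k_T_star)
    if time[-1] < plug.t_d:
        logger.warning(
            "time grid ends at %.3g s, before the dissociation start %.3g s; "
            "signal truncated",
            time[-1],
            plug.t_d,
        )

    n_r = np.zeros_like(time)
    assoc = (time >= plug.t_a) & (time < plug.t_d)
    if np.any(assoc):
        n_r[assoc] = association_solution(time[assoc] - plug.t_a, tc)
    dissoc = time >= plug.t_d
    if np.any(dissoc):
        n_r_0 = float(association_solution(plug.t_d - plug.t_a, tc))
        tc_d = tc.with_initial(n_r_0)
        n_r[dissoc] = dissociation_solution(time[dissoc] - plug.t_d, tc_d)
    return ReceivedSignal(
        time=time, N_R=n_r, N_R_max=params.N_R_max, source="analytical"
    )
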
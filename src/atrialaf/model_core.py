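"""Courtemanche–Ramirez–Nattel (CRN) human atrial cell model.

Equations follow the original publication (Courtemanche, Ramirez & Nattel,
Am J Physiol 1998, 275:H301–H321) and agree with the curated CellML
encoding of that model; no published corrections are required for this
formulation.  This module is the plain, readable reference: every current,
every gate rate, one state at a time.  The production integrators in
:mod:`atrialaf.engine` are a table-driven transcription of these same
equations, validated against this module and against a brute-force
fine-step Euler oracle.

State vector layout (21 variables, :data:`STATE_NAMES`):

==========  =====================================================
V           membrane potential, mV
m h j       I_Na activation / fast / slow inactivation gates
oa oi       I_to activation / inactivation
ua ui       I_Kur activation / inactivation
xr xs       I_Kr / I_Ks activation
d f fCa     I_CaL activation / voltage / Ca-dependent inactivation
u v w       SR Ca2+ release (ryanodine receptor) gates
Nai Ki Cai  intracellular Na+, K+, free Ca2+ (mM)
Ca_up       SR uptake-compartment Ca2+ (mM)
Ca_rel      SR release-compartment Ca2+ (mM)
==========  =====================================================

Sign convention: membrane currents are in pA/pF with inward current
negative; ``dV/dt = -(I_ion + I_stim) / C_m`` so a negative stimulus
depolarizes.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .params import (
    CA_O,
    CM,
    CMDN_MAX,
    CSQN_MAX,
    FARADAY,
    KM_CMDN,
    KM_CSQN,
    KM_TRPN,
    K_M_KO,
    K_M_NAI,
    K_M_PCA,
    K_O,
    K_Q10,
    NA_O,
    RTF,
    TAU_F_CA,
    TAU_TR,
    TAU_U,
    TRPN_MAX,
    V_I,
    V_REL,
    V_UP,
    ParameterSet,
)

STATE_NAMES: tuple[str, ...] = (
    "V", "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs",
    "d", "f", "fCa", "u", "v", "w", "Nai", "Ki", "Cai", "Ca_up", "Ca_rel",
)
N_STATE = len(STATE_NAMES)

GATE_NAMES: tuple[str, ...] = (
    "m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs", "d", "f", "fCa", "u", "v", "w",
)

#: Published CRN resting initial conditions.
INITIAL_STATE = np.array(
    [
        -81.18,        # V
        2.908e-3,      # m
        9.649e-1,      # h
        9.775e-1,      # j
        3.043e-2,      # oa
        9.992e-1,      # oi
        4.966e-3,      # ua
        9.986e-1,      # ui
        3.296e-5,      # xr
        1.869e-2,      # xs
        1.367e-4,      # d
        9.996e-1,      # f
        7.755e-1,      # fCa
        0.0,           # u (published value 2.35e-112, numerically zero)
        1.0,           # v
        9.992e-1,      # w
        1.117e1,       # Nai
        1.390e2,       # Ki
        1.013e-4,      # Cai
        1.488,         # Ca_up
        1.488,         # Ca_rel
    ],
    dtype=float,
)


def initial_state() -> np.ndarray:
    """A fresh copy of the published resting state."""
    return INITIAL_STATE.copy()


def validate_state(state: np.ndarray) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    if state.shape != (N_STATE,):
        raise ValueError(f"state must have shape ({N_STATE},), got {state.shape}")
    if not np.all(np.isfinite(state)):
        bad = [STATE_NAMES[i] for i in np.flatnonzero(~np.isfinite(state))]
        raise ValueError(f"non-finite state entries: {bad}")
    return state


@dataclass(frozen=True)
class CurrentBreakdown:
    """Instantaneous per-current densities (pA/pF, inward negative) and SR
    fluxes (mM/ms)."""

    I_Na: float
    I_K1: float
    I_to: float
    I_Kur: float
    I_Kr: float
    I_Ks: float
    I_CaL: float
    I_pCa: float
    I_NaK: float
    I_NaCa: float
    I_bNa: float
    I_bCa: float
    J_rel: float
    J_up: float
    J_up_leak: float
    J_tr: float

    MEMBRANE_CURRENTS = (
        "I_Na", "I_K1", "I_to", "I_Kur", "I_Kr", "I_Ks",
        "I_CaL", "I_pCa", "I_NaK", "I_NaCa", "I_bNa", "I_bCa",
    )

    @property
    def I_ion(self) -> float:
        """Total membrane ionic current (pA/pF) — the sum the integrator uses."""
        return float(sum(getattr(self, n) for n in self.MEMBRANE_CURRENTS))

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


# ---------------------------------------------------------------------------
# Gate kinetics: steady states and time constants as functions of V
# ---------------------------------------------------------------------------

def _safe_ratio(num: float, den: float, limit: float) -> float:
    """num/den with the removable singularity at den == 0 patched by its limit."""
    if abs(den) < 1e-12:
        return limit
    return num / den


def gate_rates(V: float, Cai: float, Fn: float) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state values and time constants (ms) for all 15 gates.

    ``Fn`` is the SR-release driving signal used by the u, v gates.
    Returns arrays ordered as :data:`GATE_NAMES`.
    """
    exp = np.exp

    # I_Na gates (Luo-Rudy style formulation adopted by CRN)
    a_m = _safe_ratio(0.32 * (V + 47.13), 1.0 - exp(-0.1 * (V + 47.13)), 3.2)
    b_m = 0.08 * exp(-V / 11.0)
    if V >= -40.0:
        a_h = 0.0
        b_h = 1.0 / (0.13 * (1.0 + exp(-(V + 10.66) / 11.1)))
        a_j = 0.0
        b_j = 0.3 * exp(-2.535e-7 * V) / (1.0 + exp(-0.1 * (V + 32.0)))
    else:
        a_h = 0.135 * exp(-(V + 80.0) / 6.8)
        b_h = 3.56 * exp(0.079 * V) + 3.1e5 * exp(0.35 * V)
        a_j = (
            (-1.2714e5 * exp(0.2444 * V) - 3.474e-5 * exp(-0.04391 * V))
            * (V + 37.78)
            / (1.0 + exp(0.311 * (V + 79.23)))
        )
        b_j = 0.1212 * exp(-0.01052 * V) / (1.0 + exp(-0.1378 * (V + 40.14)))

    m_inf, tau_m = a_m / (a_m + b_m), 1.0 / (a_m + b_m)
    h_inf, tau_h = a_h / (a_h + b_h), 1.0 / (a_h + b_h)
    j_inf, tau_j = a_j / (a_j + b_j), 1.0 / (a_j + b_j)

    # I_to
    a_oa = 0.65 / (exp(-(V + 10.0) / 8.5) + exp(-(V - 30.0) / 59.0))
    b_oa = 0.65 / (2.5 + exp((V + 82.0) / 17.0))
    tau_oa = 1.0 / (a_oa + b_oa) / K_Q10
    oa_inf = 1.0 / (1.0 + exp(-(V + 20.47) / 17.54))
    a_oi = 1.0 / (18.53 + exp((V + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + exp(-(V + 1.26) / 7.44))
    tau_oi = 1.0 / (a_oi + b_oi) / K_Q10
    oi_inf = 1.0 / (1.0 + exp((V + 43.1) / 5.3))

    # I_Kur
    a_ua = 0.65 / (exp(-(V + 10.0) / 8.5) + exp(-(V - 30.0) / 59.0))
    b_ua = 0.65 / (2.5 + exp((V + 82.0) / 17.0))
    tau_ua = 1.0 / (a_ua + b_ua) / K_Q10
    ua_inf = 1.0 / (1.0 + exp(-(V + 30.3) / 9.6))
    a_ui = 1.0 / (21.0 + exp(-(V - 185.0) / 28.0))
    b_ui = exp((V - 158.0) / 16.0)
    tau_ui = 1.0 / (a_ui + b_ui) / K_Q10
    ui_inf = 1.0 / (1.0 + exp((V - 99.45) / 27.48))

    # I_Kr
    a_xr = _safe_ratio(
        0.0003 * (V + 14.1), 1.0 - exp(-(V + 14.1) / 5.0), 0.0015
    )
    b_xr = _safe_ratio(
        7.3898e-5 * (V - 3.3328), exp((V - 3.3328) / 5.1237) - 1.0, 3.7862e-4
    )
    tau_xr = 1.0 / (a_xr + b_xr)
    xr_inf = 1.0 / (1.0 + exp(-(V + 14.1) / 6.5))

    # I_Ks
    a_xs = _safe_ratio(
        4e-5 * (V - 19.9), 1.0 - exp(-(V - 19.9) / 17.0), 6.8e-4
    )
    b_xs = _safe_ratio(
        3.5e-5 * (V - 19.9), exp((V - 19.9) / 9.0) - 1.0, 3.15e-4
    )
    tau_xs = 0.5 / (a_xs + b_xs)
    xs_inf = 1.0 / np.sqrt(1.0 + exp(-(V - 19.9) / 12.7))

    # I_CaL
    d_inf = 1.0 / (1.0 + exp(-(V + 10.0) / 8.0))
    e1 = exp(-(V + 10.0) / 6.24)
    # removable singularity at V = -10: limit 1/(2*0.035*6.24) ms
    tau_d = _safe_ratio(
        1.0 - e1, 0.035 * (V + 10.0) * (1.0 + e1), 1.0 / (2.0 * 0.035 * 6.24)
    )
    f_inf = 1.0 / (1.0 + exp((V + 28.0) / 6.9))
    tau_f = 9.0 / (0.0197 * exp(-(0.0337**2) * (V + 10.0) ** 2) + 0.02)
    fCa_inf = 1.0 / (1.0 + Cai / 0.00035)
    tau_fCa = TAU_F_CA

    # SR release gates
    u_inf = 1.0 / (1.0 + exp(-(Fn - 3.4175e-13) / 13.67e-16))
    tau_u = TAU_U
    v_inf = 1.0 - 1.0 / (1.0 + exp(-(Fn - 6.835e-14) / 13.67e-16))
    tau_v = 1.91 + 2.09 / (1.0 + exp(-(Fn - 3.4175e-13) / 13.67e-16))
    w_inf = 1.0 - 1.0 / (1.0 + exp(-(V - 40.0) / 17.0))
    tau_w = _safe_ratio(
        6.0 * (1.0 - exp(-(V - 7.9) / 5.0)),
        (1.0 + 0.3 * exp(-(V - 7.9) / 5.0)) * 1.0 * (V - 7.9),
        6.0 * 0.2 / 1.3,
    )

    infs = np.array([
        m_inf, h_inf, j_inf, oa_inf, oi_inf, ua_inf, ui_inf, xr_inf, xs_inf,
        d_inf, f_inf, fCa_inf, u_inf, v_inf, w_inf,
    ])
    taus = np.array([
        tau_m, tau_h, tau_j, tau_oa, tau_oi, tau_ua, tau_ui, tau_xr, tau_xs,
        tau_d, tau_f, tau_fCa, tau_u, tau_v, tau_w,
    ])
    return infs, taus


# ---------------------------------------------------------------------------
# Currents and state derivatives
# ---------------------------------------------------------------------------

def compute_fn(state: np.ndarray, params: ParameterSet,
               i_CaL: float, i_NaCa: float) -> float:
    """SR release driving signal Fn (CRN eq. for the u/v gates).

    Currents enter in pA (whole cell), hence the C_m factor on the
    per-pF densities.
    """
    j_rel = params.k_rel * state[13] ** 2 * state[14] * state[15] * (state[20] - state[18])
    return 1e-12 * V_REL * j_rel - (5e-13 / FARADAY) * (
        0.5 * i_CaL * CM - 0.2 * i_NaCa * CM
    )


def compute_currents(state: np.ndarray, params: ParameterSet) -> CurrentBreakdown:
    """All membrane current densities (pA/pF) and SR fluxes (mM/ms)."""
    state = validate_state(state)
    exp = np.exp
    (V, m, h, j, oa, oi, ua, ui, xr, xs, d, f, fCa, u, v, w,
     Nai, Ki, Cai, Ca_up, Ca_rel) = state

    E_Na = RTF * np.log(NA_O / Nai)
    E_K = RTF * np.log(K_O / Ki)
    E_Ca = 0.5 * RTF * np.log(CA_O / Cai)

    i_Na = params.G_Na * m**3 * h * j * (V - E_Na)
    i_K1 = params.G_K1 * (V - E_K) / (1.0 + exp(0.07 * (V + 80.0)))
    i_to = params.G_to * oa**3 * oi * (V - E_K)
    g_Kur = params.G_Kur_scale * (0.005 + 0.05 / (1.0 + exp(-(V - 15.0) / 13.0)))
    i_Kur = g_Kur * ua**3 * ui * (V - E_K)
    i_Kr = params.G_Kr * xr * (V - E_K) / (1.0 + exp((V + 15.0) / 22.4))
    i_Ks = params.G_Ks * xs**2 * (V - E_K)
    i_CaL = params.G_CaL * d * f * fCa * (V - 65.0)
    i_pCa = params.I_pCa_max * Cai / (K_M_PCA + Cai)

    sigma = (exp(NA_O / 67.3) - 1.0) / 7.0
    f_NaK = 1.0 / (
        1.0 + 0.1245 * exp(-0.1 * V / RTF) + 0.0365 * sigma * exp(-V / RTF)
    )
    i_NaK = (
        params.I_NaK_max * f_NaK
        / (1.0 + (K_M_NAI / Nai) ** 1.5)
        * K_O / (K_O + K_M_KO)
    )

    e_g = exp(params.gamma * V / RTF)
    e_g1 = exp((params.gamma - 1.0) * V / RTF)
    i_NaCa = (
        params.I_NaCa_max
        * (e_g * Nai**3 * CA_O - e_g1 * NA_O**3 * Cai)
        / (
            (params.K_mNa**3 + NA_O**3)
            * (params.K_mCa + CA_O)
            * (1.0 + params.K_sat * e_g1)
        )
    )

    i_bNa = params.G_bNa * (V - E_Na)
    i_bCa = params.G_bCa * (V - E_Ca)

    j_rel = params.k_rel * u**2 * v * w * (Ca_rel - Cai)
    j_up = params.I_up_max / (1.0 + params.K_up / Cai)
    j_up_leak = params.I_up_max * Ca_up / params.Ca_up_max
    j_tr = (Ca_up - Ca_rel) / TAU_TR

    return CurrentBreakdown(
        I_Na=i_Na, I_K1=i_K1, I_to=i_to, I_Kur=i_Kur, I_Kr=i_Kr, I_Ks=i_Ks,
        I_CaL=i_CaL, I_pCa=i_pCa, I_NaK=i_NaK, I_NaCa=i_NaCa,
        I_bNa=i_bNa, I_bCa=i_bCa,
        J_rel=j_rel, J_up=j_up, J_up_leak=j_up_leak, J_tr=j_tr,
    )


def derivatives(state: np.ndarray, params: ParameterSet,
                I_stim: float = 0.0) -> np.ndarray:
    """Time derivatives of the full state vector.

    ``I_stim`` is a stimulus current density in pA/pF (negative =
    depolarizing).  Membrane capacitance is 1 uF/cm^2, i.e. numerically
    dV/dt = -(I_ion + I_stim) in mV/ms.
    """
    state = validate_state(state)
    cur = compute_currents(state, params)
    V, Cai = state[0], state[18]

    fn = compute_fn(state, params, cur.I_CaL, cur.I_NaCa)
    infs, taus = gate_rates(V, Cai, fn)

    dstate = np.empty(N_STATE)
    dstate[0] = -(cur.I_ion + I_stim)  # C_m = 1 uF/cm^2

    gates = state[1:16]
    dstate[1:16] = (infs - gates) / taus

    # Whole-cell currents in pA for the material balances
    fvi = FARADAY * V_I
    dstate[16] = CM * (-3.0 * cur.I_NaK - 3.0 * cur.I_NaCa - cur.I_bNa - cur.I_Na) / fvi
    dstate[17] = CM * (
        2.0 * cur.I_NaK - cur.I_K1 - cur.I_to - cur.I_Kur - cur.I_Kr - cur.I_Ks
    ) / fvi

    b1 = (
        CM * (2.0 * cur.I_NaCa - cur.I_pCa - cur.I_CaL - cur.I_bCa) / (2.0 * fvi)
        + (V_UP * (cur.J_up_leak - cur.J_up) + cur.J_rel * V_REL) / V_I
    )
    b2 = (
        1.0
        + TRPN_MAX * KM_TRPN / (Cai + KM_TRPN) ** 2
        + CMDN_MAX * KM_CMDN / (Cai + KM_CMDN) ** 2
    )
    dstate[18] = b1 / b2
    dstate[19] = cur.J_up - cur.J_up_leak - cur.J_tr * V_REL / V_UP
    dstate[20] = (cur.J_tr - cur.J_rel) / (
        1.0 + CSQN_MAX * KM_CSQN / (state[20] + KM_CSQN) ** 2
    )
    return dstate
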
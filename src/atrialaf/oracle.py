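"""Brute-force fine-step Euler integrator used as a validation oracle.

This integrator deliberately shares nothing with the production path in
:mod:`atrialaf.engine`: no lookup tables, no Rush–Larsen updates, no
cached Nernst potentials — every rate equation is evaluated directly and
every variable advanced by plain forward Euler at a fixed, very small
step (0.001 ms by default).  It is far too slow for production use; its
only job is to certify, on single beats, that the fast integrator
reproduces the same action potential (APD within 1 ms, peak V within
1 mV).  The equations themselves are cross-checked against
:mod:`atrialaf.model_core` state-by-state in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .params import (
    CA_O, CM, CMDN_MAX, CSQN_MAX, FARADAY, KM_CMDN, KM_CSQN, KM_TRPN,
    K_M_KO, K_M_NAI, K_M_PCA, K_O, K_Q10, NA_O, RTF, TAU_F_CA, TAU_TR,
    TAU_U, TRPN_MAX, V_I, V_REL, V_UP, PARAM_NAMES, ParameterSet,
)


@njit(cache=True)
def _derivs(y, p, istim):
    """Direct evaluation of all 21 state derivatives (one cell).

    ``p`` is the parameter vector in table order:
    G_Na, G_bNa, G_CaL, G_bCa, G_to, G_K1, G_Kr, G_Ks, G_Kur_scale,
    I_NaK_max, I_NaCa_max, K_mCa, K_mNa, gamma, K_sat, Ca_up_max,
    I_up_max, k_rel, K_up, I_pCa_max.
    """
    (V, m, h, j, oa, oi, ua, ui, xr, xs, d, f, fca, u, vv, w,
     nai, ki, cai, caup, carel) = (
        y[0], y[1], y[2], y[3], y[4], y[5], y[6], y[7], y[8], y[9], y[10],
        y[11], y[12], y[13], y[14], y[15], y[16], y[17], y[18], y[19], y[20])

    e_na = RTF * np.log(NA_O / nai)
    e_k = RTF * np.log(K_O / ki)
    e_ca = 0.5 * RTF * np.log(CA_O / cai)

    i_na = p[0] * m**3 * h * j * (V - e_na)
    i_k1 = p[5] * (V - e_k) / (1.0 + np.exp(0.07 * (V + 80.0)))
    i_to = p[4] * oa**3 * oi * (V - e_k)
    g_kur = p[8] * (0.005 + 0.05 / (1.0 + np.exp(-(V - 15.0) / 13.0)))
    i_kur = g_kur * ua**3 * ui * (V - e_k)
    i_kr = p[6] * xr * (V - e_k) / (1.0 + np.exp((V + 15.0) / 22.4))
    i_ks = p[7] * xs**2 * (V - e_k)
    i_cal = p[2] * d * f * fca * (V - 65.0)
    i_pca = p[19] * cai / (K_M_PCA + cai)
    sigma = (np.exp(NA_O / 67.3) - 1.0) / 7.0
    f_nak = 1.0 / (1.0 + 0.1245 * np.exp(-0.1 * V / RTF)
                   + 0.0365 * sigma * np.exp(-V / RTF))
    i_nak = p[9] * f_nak / (1.0 + (K_M_NAI / nai) ** 1.5) * K_O / (K_O + K_M_KO)
    e_g = np.exp(p[13] * V / RTF)
    e_g1 = np.exp((p[13] - 1.0) * V / RTF)
    i_naca = p[10] * (e_g * nai**3 * CA_O - e_g1 * NA_O**3 * cai) / (
        (p[12] ** 3 + NA_O**3) * (p[11] + CA_O) * (1.0 + p[14] * e_g1))
    i_bna = p[1] * (V - e_na)
    i_bca = p[3] * (V - e_ca)
    i_ion = (i_na + i_k1 + i_to + i_kur + i_kr + i_ks + i_cal + i_pca
             + i_nak + i_naca + i_bna + i_bca)

    j_rel = p[17] * u**2 * vv * w * (carel - cai)
    j_up = p[16] / (1.0 + p[18] / cai)
    j_leak = p[16] * caup / p[15]
    j_tr = (caup - carel) / TAU_TR

    dy = np.empty(21)
    dy[0] = -(i_ion + istim)

    # I_Na gates
    if abs(V + 47.13) < 1e-10:
        a_m = 3.2
    else:
        a_m = 0.32 * (V + 47.13) / (1.0 - np.exp(-0.1 * (V + 47.13)))
    b_m = 0.08 * np.exp(-V / 11.0)
    if V >= -40.0:
        a_h = 0.0
        b_h = 1.0 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
        a_j = 0.0
        b_j = 0.3 * np.exp(-2.535e-7 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))
    else:
        a_h = 0.135 * np.exp(-(V + 80.0) / 6.8)
        b_h = 3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V)
        a_j = ((-1.2714e5 * np.exp(0.2444 * V) - 3.474e-5 * np.exp(-0.04391 * V))
               * (V + 37.78) / (1.0 + np.exp(0.311 * (V + 79.23))))
        b_j = 0.1212 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14)))
    dy[1] = a_m * (1.0 - m) - b_m * m
    dy[2] = a_h * (1.0 - h) - b_h * h
    dy[3] = a_j * (1.0 - j) - b_j * j

    # I_to / I_Kur gates
    a_oa = 0.65 / (np.exp(-(V + 10.0) / 8.5) + np.exp(-(V - 30.0) / 59.0))
    b_oa = 0.65 / (2.5 + np.exp((V + 82.0) / 17.0))
    oa_inf = 1.0 / (1.0 + np.exp(-(V + 20.47) / 17.54))
    dy[4] = (oa_inf - oa) * (a_oa + b_oa) * K_Q10
    a_oi = 1.0 / (18.53 + np.exp((V + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + np.exp(-(V + 1.26) / 7.44))
    oi_inf = 1.0 / (1.0 + np.exp((V + 43.1) / 5.3))
    dy[5] = (oi_inf - oi) * (a_oi + b_oi) * K_Q10
    a_ua = a_oa
    b_ua = b_oa
    ua_inf = 1.0 / (1.0 + np.exp(-(V + 30.3) / 9.6))
    dy[6] = (ua_inf - ua) * (a_ua + b_ua) * K_Q10
    a_ui = 1.0 / (21.0 + np.exp(-(V - 185.0) / 28.0))
    b_ui = np.exp((V - 158.0) / 16.0)
    ui_inf = 1.0 / (1.0 + np.exp((V - 99.45) / 27.48))
    dy[7] = (ui_inf - ui) * (a_ui + b_ui) * K_Q10

    # I_Kr / I_Ks gates
    if abs(V + 14.1) < 1e-10:
        a_xr = 0.0015
    else:
        a_xr = 0.0003 * (V + 14.1) / (1.0 - np.exp(-(V + 14.1) / 5.0))
    if abs(V - 3.3328) < 1e-10:
        b_xr = 3.7862e-4
    else:
        b_xr = 7.3898e-5 * (V - 3.3328) / (np.exp((V - 3.3328) / 5.1237) - 1.0)
    xr_inf = 1.0 / (1.0 + np.exp(-(V + 14.1) / 6.5))
    dy[8] = (xr_inf - xr) * (a_xr + b_xr)
    if abs(V - 19.9) < 1e-10:
        a_xs = 6.8e-4
        b_xs = 3.15e-4
    else:
        a_xs = 4e-5 * (V - 19.9) / (1.0 - np.exp(-(V - 19.9) / 17.0))
        b_xs = 3.5e-5 * (V - 19.9) / (np.exp((V - 19.9) / 9.0) - 1.0)
    xs_inf = 1.0 / np.sqrt(1.0 + np.exp(-(V - 19.9) / 12.7))
    dy[9] = (xs_inf - xs) * 2.0 * (a_xs + b_xs)

    # I_CaL gates
    d_inf = 1.0 / (1.0 + np.exp(-(V + 10.0) / 8.0))
    if abs(V + 10.0) < 1e-10:
        tau_d = 1.0 / (2.0 * 0.035 * 6.24)
    else:
        e1 = np.exp(-(V + 10.0) / 6.24)
        tau_d = (1.0 - e1) / (0.035 * (V + 10.0) * (1.0 + e1))
    dy[10] = (d_inf - d) / tau_d
    f_inf = 1.0 / (1.0 + np.exp((V + 28.0) / 6.9))
    tau_f = 9.0 / (0.0197 * np.exp(-(0.0337**2) * (V + 10.0) ** 2) + 0.02)
    dy[11] = (f_inf - f) / tau_f
    fca_inf = 1.0 / (1.0 + cai / 0.00035)
    dy[12] = (fca_inf - fca) / TAU_F_CA

    # SR release gates
    fn = 1e-12 * V_REL * j_rel - (5e-13 / FARADAY) * (
        0.5 * i_cal * CM - 0.2 * i_naca * CM)
    arg_u = np.minimum(np.maximum((fn - 3.4175e-13) / 13.67e-16, -200.0), 200.0)
    u_inf = 1.0 / (1.0 + np.exp(-arg_u))
    dy[13] = (u_inf - u) / TAU_U
    arg_v = np.minimum(np.maximum((fn - 6.835e-14) / 13.67e-16, -200.0), 200.0)
    v_inf = 1.0 - 1.0 / (1.0 + np.exp(-arg_v))
    tau_v = 1.91 + 2.09 / (1.0 + np.exp(-arg_u))
    dy[14] = (v_inf - vv) / tau_v
    w_inf = 1.0 - 1.0 / (1.0 + np.exp(-(V - 40.0) / 17.0))
    if abs(V - 7.9) < 1e-10:
        tau_w = 6.0 * 0.2 / 1.3
    else:
        tau_w = (6.0 * (1.0 - np.exp(-(V - 7.9) / 5.0))
                 / ((1.0 + 0.3 * np.exp(-(V - 7.9) / 5.0)) * (V - 7.9)))
    dy[15] = (w_inf - w) / tau_w

    # concentrations
    fvi = FARADAY * V_I
    dy[16] = CM * (-3.0 * i_nak - 3.0 * i_naca - i_bna - i_na) / fvi
    dy[17] = CM * (2.0 * i_nak - i_k1 - i_to - i_kur - i_kr - i_ks) / fvi
    b1 = (CM * (2.0 * i_naca - i_pca - i_cal - i_bca) / (2.0 * fvi)
          + (V_UP * (j_leak - j_up) + j_rel * V_REL) / V_I)
    b2 = (1.0 + TRPN_MAX * KM_TRPN / (cai + KM_TRPN) ** 2
          + CMDN_MAX * KM_CMDN / (cai + KM_CMDN) ** 2)
    dy[18] = b1 / b2
    dy[19] = j_up - j_leak - j_tr * V_REL / V_UP
    dy[20] = (j_tr - j_rel) / (1.0 + CSQN_MAX * KM_CSQN / (carel + KM_CSQN) ** 2)
    return dy


@njit(cache=True)
def _euler(y0, p, dt, t_end, stim_t0, stim_dur, stim_amp, dt_out):
    n_out = int(t_end / dt_out) + 1
    out_t = np.empty(n_out)
    out_v = np.empty(n_out)
    y = y0.copy()
    n_steps = int(round(t_end / dt))
    k_out = 0
    next_out = 0.0
    for k in range(n_steps + 1):
        t = k * dt
        if t >= next_out - 1e-9 and k_out < n_out:
            out_t[k_out] = t
            out_v[k_out] = y[0]
            k_out += 1
            next_out += dt_out
        if k == n_steps:
            break
        istim = stim_amp if (stim_t0 <= t < stim_t0 + stim_dur) else 0.0
        y += dt * _derivs(y, p, istim)
    return out_t[:k_out], out_v[:k_out], y


def euler_beat(state0: np.ndarray, params: ParameterSet, t_end: float = 600.0,
               dt: float = 0.001, stim_t0: float = 20.0, stim_dur: float = 2.0,
               stim_amp: float = -27.0, dt_out: float = 0.5):
    """One stimulated beat by fixed-step forward Euler.

    Returns (t, V, final_state).  ``stim_amp`` follows the membrane
    convention (negative = depolarizing).
    """
    p = params.to_vector()
    return _euler(np.asarray(state0, dtype=float), p, dt, t_end,
                  stim_t0, stim_dur, stim_amp, dt_out)


def derivatives(state: np.ndarray, params: ParameterSet,
                I_stim: float = 0.0) -> np.ndarray:
    """Direct-evaluation derivative vector (the oracle's right-hand side)."""
    return _derivs(np.asarray(state, dtype=float), params.to_vector(), I_stim)
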
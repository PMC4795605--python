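"""Table-driven integrators for cell, cable and sheet simulations.

The production scheme is Rush–Larsen for the 12 voltage-gated gating
variables (exact exponential relaxation toward the tabulated steady state)
and forward Euler for membrane potential and concentrations.  All
voltage-dependent quantities — gate steady states, Rush–Larsen decay
factors for each admissible time step, and the voltage-shaped current
coefficients — are pre-tabulated on a 0.1 mV grid with linear
interpolation.  Together with cached Nernst potentials (refreshed whenever
Na+ or K+ drifted more than 0.1% or Ca2+ more than 1%) this removes every
transcendental call from the inner loop except the rarely-exercised
SR-release sigmoids, which are branch-shortcut in their saturated range.

Time is kept as an integer number of 5 us ticks.  The admissible step
sizes are whole numbers of ticks, so stimulus edges, sample instants and
frame instants are always hit exactly.  Step-size control follows the
membrane rate: the step drops to its lower bound whenever any node moved
faster than 5 mV/ms in the previous step and grows one level per step
otherwise.

Everything here is validated against the plain reference implementation
in :mod:`atrialaf.model_core` and against a brute-force 1 us forward-Euler
oracle (see the test suite).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from numba import njit

from . import model_core as mc
from .params import (
    CA_O,
    CM,
    FARADAY,
    K_M_KO,
    K_M_NAI,
    K_M_PCA,
    K_O,
    NA_O,
    RTF,
    TAU_F_CA,
    TAU_TR,
    TAU_U,
    V_I,
    V_REL,
    V_UP,
    CMDN_MAX,
    CSQN_MAX,
    KM_CMDN,
    KM_CSQN,
    KM_TRPN,
    TRPN_MAX,
    ParameterSet,
)

TICK_MS = 0.005              # one integer time tick
V_MIN, V_MAX, DV = -120.0, 70.0, 0.1
INV_DV = 1.0 / DV
N_V = int(round((V_MAX - V_MIN) / DV)) + 1

#: indices into the state vector of the 12 voltage-gated variables,
#: in table-column order
GATE_STATE_IDX = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 15], dtype=np.int64)

# table column layout: 12 gate steady states, 12 Rush-Larsen factors,
# then the 6 voltage-shaped current coefficients
_COL_CK1 = 24
_COL_CKUR = 25
_COL_CKR = 26
_COL_CNAK = 27
_COL_NCXA = 28
_COL_NCXB = 29
N_COL = 30

# precomputed scalar combinations (avoid inner-loop divisions)
_FVI = FARADAY * V_I
_CM_FVI = CM / _FVI
_CM_2FVI = CM / (2.0 * _FVI)
_INV_TAU_TR = 1.0 / TAU_TR
_VREL_VI = V_REL / V_I
_VUP_VI = V_UP / V_I
_VREL_VUP = V_REL / V_UP
_FN_REL = 1e-12 * V_REL
_FN_CUR = (5e-13 / FARADAY) * CM

#: order of recorded current columns in trace arrays
CURRENT_NAMES = (
    "I_Na", "I_K1", "I_to", "I_Kur", "I_Kr", "I_Ks",
    "I_CaL", "I_pCa", "I_NaK", "I_NaCa", "I_bNa", "I_bCa",
)
#: full record layout: V, 12 currents, Cai, I_stim
REC_NAMES = ("V",) + CURRENT_NAMES + ("Cai", "I_stim")
N_REC = len(REC_NAMES)


class Tables(NamedTuple):
    """Pre-tabulated voltage-dependent model quantities for one parameter set."""

    tab: np.ndarray          # (n_levels, N_V, N_COL)
    dt_levels: np.ndarray    # (n_levels,) in ms
    dt_ticks: np.ndarray     # (n_levels,) int64
    rl_fca: np.ndarray       # (n_levels,) RL factor for fCa (fixed tau)
    rl_u: np.ndarray         # (n_levels,) RL factor for u (fixed tau)
    rl_v0: np.ndarray        # (n_levels,) RL factor for v at tau_v = 1.91 ms
    rl_v1: np.ndarray        # (n_levels,) RL factor for v at tau_v = 4.00 ms
    pvec: np.ndarray         # scalar parameters used directly by the kernel


# scalar-parameter vector layout for the kernel
_P_GNA, _P_GTO, _P_GKS, _P_GCAL, _P_GBNA, _P_GBCA, _P_IPCA, _P_KREL, \
    _P_IUP, _P_KUP, _P_INV_CAUPMAX = range(11)

DEFAULT_DT_LEVELS = (0.01, 0.02, 0.05, 0.1)


def build_tables(params: ParameterSet, dt_levels=DEFAULT_DT_LEVELS) -> Tables:
    """Tabulate every voltage-dependent quantity for the given parameters.

    ``dt_levels`` are the admissible step sizes (ms); each must be a whole
    number of 5 us ticks and they must be sorted ascending.
    """
    dt_levels = np.asarray(dt_levels, dtype=float)
    if dt_levels.ndim != 1 or dt_levels.size < 1:
        raise ValueError("dt_levels must be a non-empty 1D sequence")
    if np.any(np.diff(dt_levels) <= 0):
        raise ValueError("dt_levels must be sorted ascending")
    dt_ticks = np.round(dt_levels / TICK_MS).astype(np.int64)
    if not np.allclose(dt_ticks * TICK_MS, dt_levels, rtol=0, atol=1e-12):
        raise ValueError(f"every dt level must be a multiple of {TICK_MS} ms")
    # every level must be a whole multiple of the smallest, so the
    # integer-tick time line can always land exactly on event instants
    if np.any(dt_ticks % dt_ticks[0] != 0):
        raise ValueError(
            "every dt level must be an integer multiple of the smallest "
            f"(got {dt_levels.tolist()} ms)"
        )

    v = V_MIN + DV * np.arange(N_V)
    infs = np.empty((N_V, 12))
    taus = np.empty((N_V, 12))
    for k, vk in enumerate(v):
        gi, gt = mc.gate_rates(vk, 1e-4, 0.0)
        # gate_rates order: m h j oa oi ua ui xr xs d f fCa u v w
        sel = [0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 14]  # the 12 V-dependent gates
        infs[k] = gi[sel]
        taus[k] = gt[sel]

    exp = np.exp
    c_k1 = params.G_K1 / (1.0 + exp(0.07 * (v + 80.0)))
    c_kur = params.G_Kur_scale * (0.005 + 0.05 / (1.0 + exp(-(v - 15.0) / 13.0)))
    c_kr = params.G_Kr / (1.0 + exp((v + 15.0) / 22.4))
    sigma = (exp(NA_O / 67.3) - 1.0) / 7.0
    f_nak = 1.0 / (1.0 + 0.1245 * exp(-0.1 * v / RTF) + 0.0365 * sigma * exp(-v / RTF))
    c_nak = params.I_NaK_max * f_nak * K_O / (K_O + K_M_KO)
    e_g = exp(params.gamma * v / RTF)
    e_g1 = exp((params.gamma - 1.0) * v / RTF)
    denom = (
        (params.K_mNa**3 + NA_O**3)
        * (params.K_mCa + CA_O)
        * (1.0 + params.K_sat * e_g1)
    )
    ncx_a = params.I_NaCa_max * e_g * CA_O / denom
    ncx_b = params.I_NaCa_max * e_g1 * NA_O**3 / denom

    n_lev = len(dt_levels)
    tab = np.empty((n_lev, N_V, N_COL))
    for L, dt in enumerate(dt_levels):
        tab[L, :, 0:12] = infs
        tab[L, :, 12:24] = np.exp(-dt / taus)
        tab[L, :, _COL_CK1] = c_k1
        tab[L, :, _COL_CKUR] = c_kur
        tab[L, :, _COL_CKR] = c_kr
        tab[L, :, _COL_CNAK] = c_nak
        tab[L, :, _COL_NCXA] = ncx_a
        tab[L, :, _COL_NCXB] = ncx_b

    pvec = np.zeros(11)
    pvec[_P_GNA] = params.G_Na
    pvec[_P_GTO] = params.G_to
    pvec[_P_GKS] = params.G_Ks
    pvec[_P_GCAL] = params.G_CaL
    pvec[_P_GBNA] = params.G_bNa
    pvec[_P_GBCA] = params.G_bCa
    pvec[_P_IPCA] = params.I_pCa_max
    pvec[_P_KREL] = params.k_rel
    pvec[_P_IUP] = params.I_up_max
    pvec[_P_KUP] = params.K_up
    pvec[_P_INV_CAUPMAX] = 1.0 / params.Ca_up_max

    return Tables(
        tab=tab, dt_levels=dt_levels, dt_ticks=dt_ticks,
        rl_fca=np.exp(-dt_levels / TAU_F_CA),
        rl_u=np.exp(-dt_levels / TAU_U),
        rl_v0=np.exp(-dt_levels / 1.91),
        rl_v1=np.exp(-dt_levels / 4.00),
        pvec=pvec,
    )


def fresh_nernst_cache(n: int) -> np.ndarray:
    """Per-node cache of Nernst potentials; row 3-5 hold the concentrations
    at which rows 0-2 were computed (-1 forces the first refresh)."""
    ec = np.zeros((6, n))
    ec[3:] = -1.0
    return ec


# ---------------------------------------------------------------------------
# The per-node update kernel
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True, inline="always")
def _step_node(S, EC, i, tabL, rl_fca, rl_u, rl_v0, rl_v1, pvec, dt,
               istim, rec, do_rec):
    """Advance node i by dt (reaction only).  Returns dV/dt at step entry.

    ``tabL`` is the (N_V, N_COL) table slice for the current dt level;
    ``EC`` the Nernst-potential cache.  If ``do_rec``, the record row
    ``rec`` is filled with V, the 12 currents, Cai and the stimulus.
    """
    V = S[0, i]
    m = S[1, i]; h = S[2, i]; j = S[3, i]
    oa = S[4, i]; oi = S[5, i]; ua = S[6, i]; ui = S[7, i]
    xr = S[8, i]; xs = S[9, i]; d = S[10, i]; f = S[11, i]
    fca = S[12, i]; u = S[13, i]; vg = S[14, i]; w = S[15, i]
    nai = S[16, i]; ki = S[17, i]; cai = S[18, i]
    caup = S[19, i]; carel = S[20, i]

    x = (V - V_MIN) * INV_DV
    if x < 0.0:
        x = 0.0
    elif x > N_V - 1.001:
        x = N_V - 1.001
    ix = int(x)
    fr = x - ix
    t0 = tabL[ix]
    t1 = tabL[ix + 1]

    # Nernst potentials, cached against slow concentration drift (0.1%)
    dna = nai - EC[3, i]
    dk = ki - EC[4, i]
    dca = cai - EC[5, i]
    if (dna > 0.001 * nai or dna < -0.001 * nai
            or dk > 0.001 * ki or dk < -0.001 * ki
            or dca > 0.01 * cai or dca < -0.01 * cai):
        EC[0, i] = RTF * np.log(NA_O / nai)
        EC[1, i] = RTF * np.log(K_O / ki)
        EC[2, i] = 0.5 * RTF * np.log(CA_O / cai)
        EC[3, i] = nai
        EC[4, i] = ki
        EC[5, i] = cai
    e_na = EC[0, i]
    e_k = EC[1, i]
    e_ca = EC[2, i]

    i_na = pvec[_P_GNA] * m * m * m * h * j * (V - e_na)
    i_k1 = (t0[_COL_CK1] + fr * (t1[_COL_CK1] - t0[_COL_CK1])) * (V - e_k)
    i_to = pvec[_P_GTO] * oa * oa * oa * oi * (V - e_k)
    i_kur = (t0[_COL_CKUR] + fr * (t1[_COL_CKUR] - t0[_COL_CKUR])) \
        * ua * ua * ua * ui * (V - e_k)
    i_kr = (t0[_COL_CKR] + fr * (t1[_COL_CKR] - t0[_COL_CKR])) * xr * (V - e_k)
    i_ks = pvec[_P_GKS] * xs * xs * (V - e_k)
    i_cal = pvec[_P_GCAL] * d * f * fca * (V - 65.0)
    i_pca = pvec[_P_IPCA] * cai / (K_M_PCA + cai)
    r = K_M_NAI / nai
    i_nak = (t0[_COL_CNAK] + fr * (t1[_COL_CNAK] - t0[_COL_CNAK])) \
        / (1.0 + r * np.sqrt(r))
    i_naca = (t0[_COL_NCXA] + fr * (t1[_COL_NCXA] - t0[_COL_NCXA])) \
        * nai * nai * nai \
        - (t0[_COL_NCXB] + fr * (t1[_COL_NCXB] - t0[_COL_NCXB])) * cai
    i_bna = pvec[_P_GBNA] * (V - e_na)
    i_bca = pvec[_P_GBCA] * (V - e_ca)

    i_ion = (i_na + i_k1 + i_to + i_kur + i_kr + i_ks + i_cal + i_pca
             + i_nak + i_naca + i_bna + i_bca)

    if do_rec:
        rec[0] = V
        rec[1] = i_na; rec[2] = i_k1; rec[3] = i_to; rec[4] = i_kur
        rec[5] = i_kr; rec[6] = i_ks; rec[7] = i_cal; rec[8] = i_pca
        rec[9] = i_nak; rec[10] = i_naca; rec[11] = i_bna; rec[12] = i_bca
        rec[13] = cai
        rec[14] = istim

    # SR fluxes (mM/ms)
    j_rel = pvec[_P_KREL] * u * u * vg * w * (carel - cai)
    j_up = pvec[_P_IUP] * cai / (cai + pvec[_P_KUP])
    j_leak = pvec[_P_IUP] * caup * pvec[_P_INV_CAUPMAX]
    j_tr = (caup - carel) * _INV_TAU_TR

    # Rush-Larsen update of the 12 voltage-gated variables (unrolled)
    inf = t0[0] + fr * (t1[0] - t0[0]); rl = t0[12] + fr * (t1[12] - t0[12])
    m = inf + (m - inf) * rl
    inf = t0[1] + fr * (t1[1] - t0[1]); rl = t0[13] + fr * (t1[13] - t0[13])
    h = inf + (h - inf) * rl
    inf = t0[2] + fr * (t1[2] - t0[2]); rl = t0[14] + fr * (t1[14] - t0[14])
    j = inf + (j - inf) * rl
    inf = t0[3] + fr * (t1[3] - t0[3]); rl = t0[15] + fr * (t1[15] - t0[15])
    oa = inf + (oa - inf) * rl
    inf = t0[4] + fr * (t1[4] - t0[4]); rl = t0[16] + fr * (t1[16] - t0[16])
    oi = inf + (oi - inf) * rl
    inf = t0[5] + fr * (t1[5] - t0[5]); rl = t0[17] + fr * (t1[17] - t0[17])
    ua = inf + (ua - inf) * rl
    inf = t0[6] + fr * (t1[6] - t0[6]); rl = t0[18] + fr * (t1[18] - t0[18])
    ui = inf + (ui - inf) * rl
    inf = t0[7] + fr * (t1[7] - t0[7]); rl = t0[19] + fr * (t1[19] - t0[19])
    xr = inf + (xr - inf) * rl
    inf = t0[8] + fr * (t1[8] - t0[8]); rl = t0[20] + fr * (t1[20] - t0[20])
    xs = inf + (xs - inf) * rl
    inf = t0[9] + fr * (t1[9] - t0[9]); rl = t0[21] + fr * (t1[21] - t0[21])
    d = inf + (d - inf) * rl
    inf = t0[10] + fr * (t1[10] - t0[10]); rl = t0[22] + fr * (t1[22] - t0[22])
    f = inf + (f - inf) * rl
    inf = t0[11] + fr * (t1[11] - t0[11]); rl = t0[23] + fr * (t1[23] - t0[23])
    w = inf + (w - inf) * rl

    # Ca-dependent and SR-release gates
    fca_inf = 0.00035 / (0.00035 + cai)
    fca = fca_inf + (fca - fca_inf) * rl_fca

    fn = _FN_REL * j_rel - _FN_CUR * (0.5 * i_cal - 0.2 * i_naca)
    au = (fn - 3.4175e-13) * 7.315288953913679e14  # 1/13.67e-16
    # the release sigmoids are razor sharp; shortcut their saturated range
    if au > 35.0:
        u_inf = 1.0
        sig = 1.0
        rl_v = rl_v1
    elif au < -35.0:
        u_inf = 0.0
        sig = 0.0
        rl_v = rl_v0
    else:
        sig = 1.0 / (1.0 + np.exp(-au))
        u_inf = sig
        rl_v = np.exp(-dt / (1.91 + 2.09 * sig))
    u = u_inf + (u - u_inf) * rl_u
    av = (fn - 6.835e-14) * 7.315288953913679e14
    if av > 35.0:
        v_inf = 0.0
    elif av < -35.0:
        v_inf = 1.0
    else:
        v_inf = 1.0 - 1.0 / (1.0 + np.exp(-av))
    vg = v_inf + (vg - v_inf) * rl_v

    # concentrations, forward Euler (whole-cell currents in pA)
    nai += dt * _CM_FVI * (-3.0 * i_nak - 3.0 * i_naca - i_bna - i_na)
    ki += dt * _CM_FVI * (2.0 * i_nak - i_k1 - i_to - i_kur - i_kr - i_ks)
    b1 = (
        _CM_2FVI * (2.0 * i_naca - i_pca - i_cal - i_bca)
        + _VUP_VI * (j_leak - j_up) + _VREL_VI * j_rel
    )
    ct = cai + KM_TRPN
    cc = cai + KM_CMDN
    b2 = 1.0 + TRPN_MAX * KM_TRPN / (ct * ct) + CMDN_MAX * KM_CMDN / (cc * cc)
    cai += dt * b1 / b2
    caup += dt * (j_up - j_leak - j_tr * _VREL_VUP)
    cq = carel + KM_CSQN
    carel += dt * (j_tr - j_rel) / (1.0 + CSQN_MAX * KM_CSQN / (cq * cq))

    S[1, i] = m; S[2, i] = h; S[3, i] = j
    S[4, i] = oa; S[5, i] = oi; S[6, i] = ua; S[7, i] = ui
    S[8, i] = xr; S[9, i] = xs; S[10, i] = d; S[11, i] = f
    S[12, i] = fca; S[13, i] = u; S[14, i] = vg; S[15, i] = w
    S[16, i] = nai; S[17, i] = ki; S[18, i] = cai
    S[19, i] = caup; S[20, i] = carel
    return -(i_ion + istim)


# ---------------------------------------------------------------------------
# Single-cell driver
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _run_cell(S, tab, dt_levels, dt_ticks, rl_fca, rl_u, rl_v0, rl_v1, pvec,
              level_fixed,
              bcl_ticks, n_beats, offset_ticks, dur_ticks, amp,
              end_ticks, rec_start_ticks, rec_every_ticks, rec_out):
    """Paced single-cell run.  Returns (status, fail_time_ms, n_recorded).

    status 0 = ok, 1 = non-finite state encountered.
    ``level_fixed`` selects one dt level (single-cell runs use a fixed
    step).  Records every ``rec_every_ticks`` from ``rec_start_ticks`` on.
    """
    t = np.int64(0)
    n_rec = 0
    dt = dt_levels[level_fixed]
    step = dt_ticks[level_fixed]
    tabL = tab[level_fixed]
    rlf = rl_fca[level_fixed]
    rlu = rl_u[level_fixed]
    rv0 = rl_v0[level_fixed]
    rv1 = rl_v1[level_fixed]
    EC = np.zeros((6, 1))
    EC[3:] = -1.0
    rec_row = np.empty(N_REC)
    next_rec = rec_start_ticks
    check = 0
    while t < end_ticks:
        # stimulus at step entry
        istim = 0.0
        if bcl_ticks > 0 and t >= offset_ticks:
            k = (t - offset_ticks) // bcl_ticks
            ph = (t - offset_ticks) - k * bcl_ticks
            if k < n_beats and ph < dur_ticks:
                istim = amp
        do_rec = t >= next_rec
        dv = _step_node(S, EC, 0, tabL, rlf, rlu, rv0, rv1, pvec, dt,
                        istim, rec_row, do_rec)
        S[0, 0] = S[0, 0] + dt * dv
        if do_rec:
            for c in range(N_REC):
                rec_out[n_rec, c] = rec_row[c]
            n_rec += 1
            next_rec += rec_every_ticks
        t += step
        check += 1
        if check >= 1000:
            check = 0
            if not np.isfinite(S[0, 0]):
                return 1, t * TICK_MS, n_rec
    if not np.isfinite(S[0, 0]):
        return 1, end_ticks * TICK_MS, n_rec
    return 0, 0.0, n_rec


# ---------------------------------------------------------------------------
# Cable driver (1D monodomain, operator splitting)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _run_cable(S, EC, tab, dt_levels, dt_ticks, rl_fca, rl_u, rl_v0, rl_v1,
               pvec, d_over_dx2,
               stim_onsets, dur_ticks, amp, n_stim_nodes,
               end_ticks, probe_idx, probe_every_ticks, probe_out,
               full_every_ticks, full_out):
    """1D cable with stimuli applied to the first ``n_stim_nodes`` nodes.

    ``stim_onsets`` is a sorted int64 array of stimulus onset ticks.
    Records the probe-node V every ``probe_every_ticks`` into
    ``probe_out`` and (optionally, if ``full_every_ticks > 0``) all-node V
    into ``full_out``.  Returns (status, fail_time_ms, n_probe, n_full).
    """
    n = S.shape[1]
    n_lev = len(dt_ticks)
    t = np.int64(0)
    level = 0
    max_dv = 1e9  # force the small step initially
    n_probe = 0
    n_full = 0
    next_probe = np.int64(0)
    next_full = np.int64(0) if full_every_ticks > 0 else np.int64(-1)
    stim_i = 0
    rec_dummy = np.empty(N_REC)
    vnew = np.empty(n)
    while t < end_ticks:
        # desired level from the previous step's max |dV/dt|
        if max_dv > 5.0:
            want = 0
        else:
            want = level + 1
            if want > n_lev - 1:
                want = n_lev - 1
        # do not step across the next stimulus edge or record instant
        while stim_i < len(stim_onsets) and stim_onsets[stim_i] + dur_ticks <= t:
            stim_i += 1
        limit = end_ticks - t
        if stim_i < len(stim_onsets):
            on = stim_onsets[stim_i]
            if t < on:
                if on - t < limit:
                    limit = on - t
            else:
                if (on + dur_ticks) - t < limit:
                    limit = (on + dur_ticks) - t
        if next_probe > t and next_probe - t < limit:
            limit = next_probe - t
        if next_full > t and next_full - t < limit:
            limit = next_full - t
        while want > 0 and dt_ticks[want] > limit:
            want -= 1
        level = want
        dt = dt_levels[level]
        step = dt_ticks[level]
        tabL = tab[level]
        rlf = rl_fca[level]
        rlu = rl_u[level]
        rv0 = rl_v0[level]
        rv1 = rl_v1[level]

        stim_on = (
            stim_i < len(stim_onsets)
            and t >= stim_onsets[stim_i]
            and t < stim_onsets[stim_i] + dur_ticks
        )

        # record at step entry
        if t == next_probe:
            probe_out[n_probe] = S[0, probe_idx]
            n_probe += 1
            next_probe += probe_every_ticks
        if t == next_full:
            for i2 in range(n):
                full_out[n_full, i2] = S[0, i2]
            n_full += 1
            next_full += full_every_ticks

        max_dv = 0.0
        for i in range(n):
            istim = amp if (stim_on and i < n_stim_nodes) else 0.0
            dv = _step_node(S, EC, i, tabL, rlf, rlu, rv0, rv1, pvec, dt,
                            istim, rec_dummy, False)
            adv = abs(dv)
            if adv > max_dv:
                max_dv = adv
            vnew[i] = S[0, i] + dt * dv
        # diffusion, zero-flux ends
        c = dt * d_over_dx2
        for i in range(n):
            vl = vnew[i - 1] if i > 0 else vnew[1]
            vr = vnew[i + 1] if i < n - 1 else vnew[n - 2]
            S[0, i] = vnew[i] + c * (vl - 2.0 * vnew[i] + vr)
        t += step
        if not np.isfinite(S[0, n // 2]):
            return 1, t * TICK_MS, n_probe, n_full
    # final record instants falling exactly at end
    if t == next_probe and n_probe < probe_out.shape[0]:
        probe_out[n_probe] = S[0, probe_idx]
        n_probe += 1
    if t == next_full and full_every_ticks > 0 and n_full < full_out.shape[0]:
        for i2 in range(n):
            full_out[n_full, i2] = S[0, i2]
        n_full += 1
    return 0, 0.0, n_probe, n_full


# ---------------------------------------------------------------------------
# 2D sheet driver (cross-field S1-S2)
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _run_sheet(S, EC, tab, dt_levels, dt_ticks, rl_fca, rl_u, rl_v0, rl_v1,
               pvec, nx, ny, d_over_dx2,
               s1_ticks, s2_ticks, dur_ticks, amp, s1_cols, s2_rows,
               end_ticks, frame_every_ticks, frames_out):
    """2D monodomain sheet with the cross-field reentry-induction protocol.

    S1 stimulates the first ``s1_cols`` columns at ``s1_ticks``; S2
    stimulates the first ``s2_rows`` rows at ``s2_ticks`` (orthogonal
    half-field).  Node (row y, col x) is flattened to index y*nx + x.
    V frames (float32) are stored every ``frame_every_ticks``.
    Returns (status, fail_time_ms, n_frames).
    """
    n = nx * ny
    n_lev = len(dt_ticks)
    t = np.int64(0)
    level = 0
    max_dv = 1e9
    n_frames = 0
    next_frame = np.int64(0)
    rec_dummy = np.empty(N_REC)
    vnew = np.empty(n)
    edges = np.empty(4, dtype=np.int64)
    edges[0] = s1_ticks
    edges[1] = s1_ticks + dur_ticks
    edges[2] = s2_ticks
    edges[3] = s2_ticks + dur_ticks
    while t < end_ticks:
        if max_dv > 5.0:
            want = 0
        else:
            want = level + 1
            if want > n_lev - 1:
                want = n_lev - 1
        limit = end_ticks - t
        for e in range(4):
            if edges[e] > t and edges[e] - t < limit:
                limit = edges[e] - t
        if next_frame > t and next_frame - t < limit:
            limit = next_frame - t
        while want > 0 and dt_ticks[want] > limit:
            want -= 1
        level = want
        dt = dt_levels[level]
        step = dt_ticks[level]
        tabL = tab[level]
        rlf = rl_fca[level]
        rlu = rl_u[level]
        rv0 = rl_v0[level]
        rv1 = rl_v1[level]

        s1_on = t >= s1_ticks and t < s1_ticks + dur_ticks
        s2_on = t >= s2_ticks and t < s2_ticks + dur_ticks

        if t == next_frame:
            for i2 in range(n):
                frames_out[n_frames, i2] = S[0, i2]
            n_frames += 1
            next_frame += frame_every_ticks

        max_dv = 0.0
        for y in range(ny):
            row0 = y * nx
            s2_here = s2_on and y < s2_rows
            for x in range(nx):
                i = row0 + x
                istim = 0.0
                if s1_on and x < s1_cols:
                    istim = amp
                if s2_here:
                    istim = amp
                dv = _step_node(S, EC, i, tabL, rlf, rlu, rv0, rv1, pvec, dt,
                                istim, rec_dummy, False)
                adv = abs(dv)
                if adv > max_dv:
                    max_dv = adv
                vnew[i] = S[0, i] + dt * dv
        # 5-point Laplacian, zero-flux boundaries
        c = dt * d_over_dx2
        for y in range(ny):
            yl = y - 1 if y > 0 else 1
            yr = y + 1 if y < ny - 1 else ny - 2
            row0 = y * nx
            rowl = yl * nx
            rowr = yr * nx
            for x in range(nx):
                xl = x - 1 if x > 0 else 1
                xr = x + 1 if x < nx - 1 else nx - 2
                i = row0 + x
                lap = (vnew[row0 + xl] + vnew[row0 + xr]
                       + vnew[rowl + x] + vnew[rowr + x] - 4.0 * vnew[i])
                S[0, i] = vnew[i] + c * lap
        t += step
        if not np.isfinite(S[0, n // 2]) or abs(S[0, n // 2]) > 200.0:
            return 1, t * TICK_MS, n_frames
    if t == next_frame and n_frames < frames_out.shape[0]:
        for i2 in range(n):
            frames_out[n_frames, i2] = S[0, i2]
        n_frames += 1
    return 0, 0.0, n_frames
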
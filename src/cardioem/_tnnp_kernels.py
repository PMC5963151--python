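"""Numba kernels for the ten Tusscher-Noble-Noble-Panfilov (2004) human
ventricular membrane model.

State-vector layout (index constants below): membrane potential, twelve
Hodgkin-Huxley-type gates plus the calcium-release gate, and the four ionic
concentrations.  All voltages in mV, time in ms, currents in pA/pF,
concentrations in mM.  Cell-type selects the transient-outward and slow
delayed-rectifier conductances (epi/endo/mid).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# --- state indices -----------------------------------------------------------
IV = 0
IM = 1
IH = 2
IJ = 3
ID = 4
IF = 5
IFCA = 6
IR = 7
IS = 8
IXR1 = 9
IXR2 = 10
IXS = 11
IG = 12
ICAI = 13
ICASR = 14
INAI = 15
IKI = 16
NSTATE = 17

GATE_INDICES = (IM, IH, IJ, ID, IF, IFCA, IR, IS, IXR1, IXR2, IXS, IG)

# --- physical constants ------------------------------------------------------
R_GAS = 8314.472      # mJ/(mol K)
T_KELVIN = 310.0      # K
F_CONST = 96485.3415  # C/mol
RTONF = R_GAS * T_KELVIN / F_CONST

KO = 5.4     # mM
NAO = 140.0  # mM
CAO = 2.0    # mM

CM_CAP = 0.185     # µF membrane capacitance used in concentration updates
V_C = 0.016404     # µL cytoplasmic volume
V_SR = 0.001094    # µL SR volume

G_NA = 14.838
G_K1 = 5.405
G_KR = 0.096
G_CAL = 0.000175
G_PK = 0.0146
G_PCA = 0.825
K_PCA = 0.0005
G_BNA = 0.00029
G_BCA = 0.000592
P_KNA = 0.03

K_NACA = 1000.0
KM_NAI = 87.5
KM_CA = 1.38
K_SAT = 0.1
GAMMA = 0.35
ALPHA_NACA = 2.5

P_NAK = 1.362
KM_K = 1.0
KM_NA = 40.0

# SR calcium handling
A_REL = 0.016464
B_REL = 0.25
C_REL = 0.008232
V_MAXUP = 0.000425
K_UP = 0.00025
V_LEAK = 8.0e-5

BUF_C = 0.15
K_BUF_C = 0.001
BUF_SR = 10.0
K_BUF_SR = 0.3

# cell-type codes
EPI = 0
ENDO = 1
MID = 2


@njit(cache=False)
def _gto_gks(cell_type: int):
    if cell_type == EPI:
        return 0.294, 0.245
    elif cell_type == ENDO:
        return 0.073, 0.245
    else:  # MID
        return 0.294, 0.062


@njit(cache=False)
def currents(y: np.ndarray, cell_type: int) -> np.ndarray:
    """Evaluate the twelve transmembrane currents (pA/pF).

    Returns [i_na, i_k1, i_to, i_kr, i_ks, i_cal, i_naca, i_nak,
             i_pca, i_pk, i_bca, i_bna].
    """
    v = y[IV]
    cai = y[ICAI]
    nai = y[INAI]
    ki = y[IKI]
    g_to, g_ks = _gto_gks(cell_type)

    ena = RTONF * np.log(NAO / nai)
    ek = RTONF * np.log(KO / ki)
    eks = RTONF * np.log((KO + P_KNA * NAO) / (ki + P_KNA * nai))
    eca = 0.5 * RTONF * np.log(CAO / cai)

    i_na = G_NA * y[IM] ** 3 * y[IH] * y[IJ] * (v - ena)

    ak1 = 0.1 / (1.0 + np.exp(0.06 * (v - ek - 200.0)))
    bk1 = (
        3.0 * np.exp(0.0002 * (v - ek + 100.0)) + np.exp(0.1 * (v - ek - 10.0))
    ) / (1.0 + np.exp(-0.5 * (v - ek)))
    xk1_inf = ak1 / (ak1 + bk1)
    i_k1 = G_K1 * np.sqrt(KO / 5.4) * xk1_inf * (v - ek)

    i_to = g_to * y[IR] * y[IS] * (v - ek)
    i_kr = G_KR * np.sqrt(KO / 5.4) * y[IXR1] * y[IXR2] * (v - ek)
    i_ks = g_ks * y[IXS] ** 2 * (v - eks)

    vfort = v * F_CONST / (R_GAS * T_KELVIN)
    e2v = np.exp(2.0 * vfort)
    if np.abs(v) < 1.0e-6:
        # L'Hopital limit of the GHG driving term at v = 0
        i_cal = G_CAL * y[ID] * y[IF] * y[IFCA] * 2.0 * F_CONST * (cai - 0.341 * CAO)
    else:
        i_cal = (
            G_CAL * y[ID] * y[IF] * y[IFCA] * 4.0 * v * F_CONST**2 / (R_GAS * T_KELVIN)
            * (cai * e2v - 0.341 * CAO) / (e2v - 1.0)
        )

    i_naca = (
        K_NACA
        * (np.exp(GAMMA * vfort) * nai**3 * CAO
           - np.exp((GAMMA - 1.0) * vfort) * NAO**3 * cai * ALPHA_NACA)
        / ((KM_NAI**3 + NAO**3) * (KM_CA + CAO)
           * (1.0 + K_SAT * np.exp((GAMMA - 1.0) * vfort)))
    )

    i_nak = (
        P_NAK * KO * nai
        / ((KO + KM_K) * (nai + KM_NA)
           * (1.0 + 0.1245 * np.exp(-0.1 * vfort) + 0.0353 * np.exp(-vfort)))
    )

    i_pca = G_PCA * cai / (K_PCA + cai)
    i_pk = G_PK * (v - ek) / (1.0 + np.exp((25.0 - v) / 5.98))
    i_bna = G_BNA * (v - ena)
    i_bca = G_BCA * (v - eca)

    out = np.empty(12)
    out[0] = i_na
    out[1] = i_k1
    out[2] = i_to
    out[3] = i_kr
    out[4] = i_ks
    out[5] = i_cal
    out[6] = i_naca
    out[7] = i_nak
    out[8] = i_pca
    out[9] = i_pk
    out[10] = i_bca
    out[11] = i_bna
    return out


@njit(cache=False)
def gate_targets(y: np.ndarray, cell_type: int):
    """Steady-state values and time constants (ms) for the twelve gates.

    Returns (inf, tau) arrays ordered as GATE_INDICES.  The calcium-dependent
    gates (fCa, g) carry their voltage-conditional freeze in `step`.
    """
    v = y[IV]
    cai = y[ICAI]

    inf = np.empty(12)
    tau = np.empty(12)

    # m
    inf[0] = 1.0 / (1.0 + np.exp((-56.86 - v) / 9.03)) ** 2
    am = 1.0 / (1.0 + np.exp((-60.0 - v) / 5.0))
    bm = 0.1 / (1.0 + np.exp((v + 35.0) / 5.0)) + 0.1 / (1.0 + np.exp((v - 50.0) / 200.0))
    tau[0] = am * bm
    # h
    inf[1] = 1.0 / (1.0 + np.exp((v + 71.55) / 7.43)) ** 2
    if v < -40.0:
        ah = 0.057 * np.exp(-(v + 80.0) / 6.8)
        bh = 2.7 * np.exp(0.079 * v) + 3.1e5 * np.exp(0.3485 * v)
    else:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + np.exp(-(v + 10.66) / 11.1)))
    tau[1] = 1.0 / (ah + bh)
    # j
    inf[2] = inf[1]
    if v < -40.0:
        aj = (
            (-2.5428e4 * np.exp(0.2444 * v) - 6.948e-6 * np.exp(-0.04391 * v))
            * (v + 37.78) / (1.0 + np.exp(0.311 * (v + 79.23)))
        )
        bj = 0.02424 * np.exp(-0.01052 * v) / (1.0 + np.exp(-0.1378 * (v + 40.14)))
    else:
        aj = 0.0
        bj = 0.6 * np.exp(0.057 * v) / (1.0 + np.exp(-0.1 * (v + 32.0)))
    tau[2] = 1.0 / (aj + bj)
    # d
    inf[3] = 1.0 / (1.0 + np.exp((-5.0 - v) / 7.5))
    ad = 1.4 / (1.0 + np.exp((-35.0 - v) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + np.exp((v + 5.0) / 5.0))
    gd = 1.0 / (1.0 + np.exp((50.0 - v) / 20.0))
    tau[3] = ad * bd + gd
    # f
    inf[4] = 1.0 / (1.0 + np.exp((v + 20.0) / 7.0))
    tau[4] = (
        1125.0 * np.exp(-((v + 27.0) ** 2) / 240.0)
        + 80.0
        + 165.0 / (1.0 + np.exp((25.0 - v) / 10.0))
    )
    # fCa
    afca = 1.0 / (1.0 + (cai / 0.000325) ** 8)
    bfca = 0.1 / (1.0 + np.exp((cai - 0.0005) / 0.0001))
    gfca = 0.2 / (1.0 + np.exp((cai - 0.00075) / 0.0008))
    inf[5] = (afca + bfca + gfca + 0.23) / 1.46
    tau[5] = 2.0
    # r, s (epi/mid share r/s kinetics; endo s differs)
    inf[6] = 1.0 / (1.0 + np.exp((20.0 - v) / 6.0))
    tau[6] = 9.5 * np.exp(-((v + 40.0) ** 2) / 1800.0) + 0.8
    if cell_type == ENDO:
        inf[7] = 1.0 / (1.0 + np.exp((v + 28.0) / 5.0))
        tau[7] = 1000.0 * np.exp(-((v + 67.0) ** 2) / 1000.0) + 8.0
    else:
        inf[7] = 1.0 / (1.0 + np.exp((v + 20.0) / 5.0))
        tau[7] = 85.0 * np.exp(-((v + 45.0) ** 2) / 320.0) + 5.0 / (1.0 + np.exp((v - 20.0) / 5.0)) + 3.0
    # xr1
    inf[8] = 1.0 / (1.0 + np.exp((-26.0 - v) / 7.0))
    axr1 = 450.0 / (1.0 + np.exp((-45.0 - v) / 10.0))
    bxr1 = 6.0 / (1.0 + np.exp((v + 30.0) / 11.5))
    tau[8] = axr1 * bxr1
    # xr2
    inf[9] = 1.0 / (1.0 + np.exp((v + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + np.exp((-60.0 - v) / 20.0))
    bxr2 = 1.12 / (1.0 + np.exp((v - 60.0) / 20.0))
    tau[9] = axr2 * bxr2
    # xs
    inf[10] = 1.0 / (1.0 + np.exp((-5.0 - v) / 14.0))
    axs = 1100.0 / np.sqrt(1.0 + np.exp((-10.0 - v) / 6.0))
    bxs = 1.0 / (1.0 + np.exp((v - 60.0) / 20.0))
    tau[10] = axs * bxs
    # g (SR release gate)
    if cai < 0.00035:
        inf[11] = 1.0 / (1.0 + (cai / 0.00035) ** 6)
    else:
        inf[11] = 1.0 / (1.0 + (cai / 0.00035) ** 16)
    tau[11] = 2.0
    return inf, tau


@njit(cache=False)
def step(y: np.ndarray, dt: float, i_stim: float, cell_type: int) -> float:
    """Advance the state one forward-Euler step in place; returns i_ion (pA/pF).

    Gating variables use the Rush-Larsen exponential update, which is exact
    for the locally linear gate ODEs and stable at dt = 0.01 ms.  The
    calcium-dependent inactivation gates (fCa, g) freeze while depolarized
    (v > -60 mV) whenever their steady state exceeds the current value, as
    in the published formulation.
    """
    v = y[IV]
    cai = y[ICAI]
    casr = y[ICASR]

    cur = currents(y, cell_type)
    i_ion = (
        cur[0] + cur[1] + cur[2] + cur[3] + cur[4] + cur[5]
        + cur[6] + cur[7] + cur[8] + cur[9] + cur[10] + cur[11]
    )

    inf, tau = gate_targets(y, cell_type)

    # SR fluxes (mM/ms)
    i_rel = (A_REL * casr**2 / (B_REL**2 + casr**2) + C_REL) * y[ID] * y[IG]
    i_up = V_MAXUP / (1.0 + (K_UP / cai) ** 2)
    i_leak = V_LEAK * (casr - cai)

    # buffered calcium updates
    ca_free_flux = (
        i_leak - i_up + i_rel
        - (cur[5] + cur[10] + cur[8] - 2.0 * cur[6]) * CM_CAP / (2.0 * V_C * F_CONST)
    )
    buf_c = 1.0 / (1.0 + BUF_C * K_BUF_C / (cai + K_BUF_C) ** 2)
    dcai = buf_c * ca_free_flux
    buf_sr = 1.0 / (1.0 + BUF_SR * K_BUF_SR / (casr + K_BUF_SR) ** 2)
    dcasr = buf_sr * (V_C / V_SR) * (i_up - i_rel - i_leak)

    dnai = -(cur[0] + cur[11] + 3.0 * cur[7] + 3.0 * cur[6]) * CM_CAP / (V_C * F_CONST)
    dki = -(
        cur[1] + cur[2] + cur[3] + cur[4] - 2.0 * cur[7] + cur[9] + i_stim
    ) * CM_CAP / (V_C * F_CONST)

    # Rush-Larsen gate updates
    for k in range(12):
        idx = GATE_INDICES[k]
        if (idx == IFCA or idx == IG) and inf[k] > y[idx] and v > -60.0:
            continue  # gate frozen while depolarized
        y[idx] = inf[k] + (y[idx] - inf[k]) * np.exp(-dt / tau[k])

    y[ICAI] = cai + dt * dcai
    y[ICASR] = casr + dt * dcasr
    y[INAI] = y[INAI] + dt * dnai
    y[IKI] = y[IKI] + dt * dki
    y[IV] = v - dt * (i_ion + i_stim)
    return i_ion


@njit(cache=False)
def pace(
    y: np.ndarray,
    n_beats: int,
    bcl_ms: float,
    dt: float,
    stim_amp: float,
    stim_dur_ms: float,
    cell_type: int,
    record_stride: int,
):
    """Pace the cell for n_beats at the given cycle length, recording v and Cai.

    Returns (time_ms, v_mv, cai_mM) sampled every ``record_stride`` steps.
    Raises no exceptions inside numba; divergence is signalled by returning
    early with the step count encoded in the final time value being negative.
    """
    steps_per_beat = int(np.round(bcl_ms / dt))
    n_total = steps_per_beat * n_beats
    n_rec = n_total // record_stride + 1
    t_out = np.empty(n_rec)
    v_out = np.empty(n_rec)
    ca_out = np.empty(n_rec)
    stim_steps = int(np.round(stim_dur_ms / dt))
    r = 0
    for n in range(n_total):
        if n % record_stride == 0:
            t_out[r] = n * dt
            v_out[r] = y[IV]
            ca_out[r] = y[ICAI]
            r += 1
        in_stim = (n % steps_per_beat) < stim_steps
        i_stim = stim_amp if in_stim else 0.0
        step(y, dt, i_stim, cell_type)
        if np.abs(y[IV]) > 200.0:
            t_out[r - 1] = -float(n)  # divergence sentinel
            return t_out[:r], v_out[:r], ca_out[:r]
    t_out[r] = n_total * dt
    v_out[r] = y[IV]
    ca_out[r] = y[ICAI]
    return t_out[: r + 1], v_out[: r + 1], ca_out[: r + 1]
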
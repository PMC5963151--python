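"""Myofilament cross-bridge dynamics: calcium-driven active tension,
shortening and ATP consumption.

The model is a transcription of the Rice et al. (2008) approximate
cross-bridge formulation: calcium binds low/high-affinity troponin
regulatory units whose occupancy gates the nonpermissive -> permissive
transition (N <-> P), and permissive units cycle through strongly bound
pre-rotation (XBpreR) and post-rotation (XBpostR) states.  Mean distortions
of the two attached states evolve with their own ODEs and weight the force
sum; thick/thin filament overlap modulates recruitment with sarcomere
length.  Active tension is the overlap-scaled, distortion-weighted sum of
attached fractions, normalized to the maximal steady-state value and scaled
to kPa.  ATP consumption is the ATP-hydrolysing detachment flux
gxb * XBpostR weighted by overlap.

Rate constants are the published baseline values (units converted to ms);
no temperature rescaling is applied.  Single-cell loading uses an
afterloaded force balance: the muscle holds its initial length until total
(active + passive) tension exceeds the applied load, then shortens
quasi-statically against it through a small viscous term.  A load far above
peak tension (the 1000 kPa convention) therefore realizes the isometric
protocol; a hard length clamp is available as an equivalent alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .calcium import CalciumTransient
from .exceptions import InvalidParameterError, NumericDomainError

__all__ = [
    "CrossBridgeState",
    "TwitchResult",
    "init_xb_state",
    "step_xb",
    "active_tension",
    "run_twitch",
    "atp_consumption",
    "steady_state_force_ca",
    "F_SCALE_KPA",
]

# --- published rate constants, converted to per-ms / per-µM -----------------
KON = 0.050        # troponin Ca on-rate, 1/(µM ms)
KOFF_L = 0.250     # low-affinity off-rate, 1/ms
KOFF_H = 0.025     # high-affinity off-rate, 1/ms
PERM50 = 0.5       # half-activation of the permissivity switch
NPERM = 15.0       # cooperativity of the switch
KN_P = 0.50        # N -> P base rate, 1/ms
KP_N = 0.05        # P -> N base rate, 1/ms
FAPP = 0.500       # P -> XBpreR attachment, 1/ms
GAPP = 0.070       # XBpreR -> P detachment, 1/ms
GSLMOD = 6.0       # SL modulation of gapp
HF_R = 2.000       # XBpreR -> XBpostR rotation, 1/ms
HFMDC = 5.0        # strain modulation of rotation
HB_R = 0.400       # back rotation, 1/ms
GXB = 0.070        # ATP-consuming detachment, 1/ms
SIGMA_P = 8.0      # strain sensitivity of gxb, shortening side
SIGMA_N = 1.0      # lengthening side
X_0 = 0.007        # µm, power-stroke distortion
X_PSI = 2.0        # strain-ODE scaling

# sarcomere geometry (µm)
SL_MAX = 2.4
SL_MIN = 1.4
LEN_THIN = 1.2
LEN_THICK = 1.65
LEN_HBARE = 0.1
SL_REST = 1.9

# passive titin-like elasticity (normalized force units)
PCON_T = 0.002
PEXP_T = 10.0

#: Tension scale: maximal steady-state Ca-activated tension at full overlap.
F_SCALE_KPA = 120.0

_HFMD_CAP = 20.0   # numerical cap on the strain modulation of rotation

# steady-state attached fractions at zero distortion (the force normalizer)
_SS_DENOM = (
    GXB * HF_R + FAPP * HF_R + GXB * GAPP + HB_R * FAPP + HB_R * GAPP + GXB * FAPP
)
SS_XBPRER = (HB_R * FAPP + GXB * FAPP) / _SS_DENOM
SS_XBPOSTR = FAPP * HF_R / _SS_DENOM


@dataclass
class CrossBridgeState:
    """Regulatory-unit and cross-bridge fractions plus sarcomere length.

    Fractions n_xb + p_xb + xb_prer + xb_postr = 1; trpn_ca_l / trpn_ca_h are
    the Ca-bound fractions of low/high-affinity troponin units; sl is
    sarcomere length (µm); x_prer / x_postr are mean distortions (µm).
    """

    n_xb: float
    p_xb: float
    xb_prer: float
    xb_postr: float
    trpn_ca_l: float
    trpn_ca_h: float
    sl: float
    x_prer: float
    x_postr: float

    def as_array(self) -> np.ndarray:
        return np.array([
            self.n_xb, self.p_xb, self.xb_prer, self.xb_postr,
            self.trpn_ca_l, self.trpn_ca_h, self.sl, self.x_prer, self.x_postr,
        ])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "CrossBridgeState":
        return cls(*[float(x) for x in y])

    def fraction_sum(self) -> float:
        return self.n_xb + self.p_xb + self.xb_prer + self.xb_postr


def init_xb_state(sl: float = 2.2) -> CrossBridgeState:
    """Fully relaxed state: all regulatory units nonpermissive, no attached XBs."""
    if not (SL_MIN <= sl <= SL_MAX):
        raise InvalidParameterError(f"sl = {sl} outside [{SL_MIN}, {SL_MAX}] µm")
    return CrossBridgeState(
        n_xb=1.0, p_xb=0.0, xb_prer=0.0, xb_postr=0.0,
        trpn_ca_l=0.0, trpn_ca_h=0.0, sl=sl, x_prer=0.0, x_postr=X_0,
    )


@njit(cache=False)
def _overlap(sl: float):
    sovr_ze = min(LEN_THICK / 2.0, sl / 2.0)
    sovr_cle = max(sl / 2.0 - (sl - LEN_THIN), LEN_HBARE / 2.0)
    len_sovr = max(sovr_ze - sovr_cle, 0.0)
    sovf_thick = len_sovr * 2.0 / (LEN_THICK - LEN_HBARE)
    sovf_thin = len_sovr / LEN_THIN
    return sovf_thick, sovf_thin


@njit(cache=False)
def _passive_norm(sl: float) -> float:
    d = sl - SL_REST
    s = 1.0 if d >= 0 else -1.0
    return s * PCON_T * (math.exp(PEXP_T * abs(d)) - 1.0)


@njit(cache=False)
def _active_norm(y: np.ndarray) -> float:
    sovf_thick, _ = _overlap(y[6])
    return sovf_thick * (y[7] * y[2] + y[8] * y[3]) / (X_0 * SS_XBPOSTR)


@njit(cache=False)
def _rates(y: np.ndarray, ca_um: float):
    """Strain- and Ca-modulated transition rates at the current state."""
    sovf_thick, sovf_thin = _overlap(y[6])
    trop_reg = (1.0 - sovf_thin) * y[4] + sovf_thin * y[5]
    if trop_reg < 1.0e-12:
        trop_reg = 1.0e-12
    permtot = math.sqrt(1.0 / (1.0 + (PERM50 / trop_reg) ** NPERM))
    inprmt = min(1.0 / permtot, 100.0)
    kn_pt = KN_P * permtot
    kp_nt = KP_N * inprmt

    fappt = FAPP
    gappt = GAPP * (1.0 + (1.0 - sovf_thick) * GSLMOD)
    xpr = y[7]
    hfmd = math.exp(-math.copysign(1.0, xpr) * HFMDC * (xpr / X_0) ** 2)
    if hfmd > _HFMD_CAP:
        hfmd = _HFMD_CAP
    hft = HF_R * hfmd
    hbt = HB_R
    xpo = y[8]
    if xpo < X_0:
        gxbmd = math.exp(SIGMA_P * ((X_0 - xpo) / X_0) ** 2)
    else:
        gxbmd = math.exp(SIGMA_N * ((xpo - X_0) / X_0) ** 2)
    if gxbmd > _HFMD_CAP:
        gxbmd = _HFMD_CAP
    gxbt = GXB * gxbmd
    return kn_pt, kp_nt, fappt, gappt, hft, hbt, gxbt


@njit(cache=False)
def _step_kernel(y: np.ndarray, ca_um: float, dt: float, mode_clamp: int,
                 load_kpa: float, sl0: float, visc: float, f_scale: float) -> float:
    """Advance one step in place; returns total tension (kPa) at entry state."""
    kn_pt, kp_nt, fappt, gappt, hft, hbt, gxbt = _rates(y, ca_um)

    # troponin Ca binding
    dtl = KON * ca_um * (1.0 - y[4]) - KOFF_L * y[4]
    dth = KON * ca_um * (1.0 - y[5]) - KOFF_H * y[5]

    # regulatory/XB fractions (sum conserved exactly)
    dn = -kn_pt * y[0] + kp_nt * y[1]
    dpre = fappt * y[1] - gappt * y[2] - hft * y[2] + hbt * y[3]
    dpost = hft * y[2] - hbt * y[3] - gxbt * y[3]
    dp = -(dn + dpre + dpost)

    # force balance -> length dynamics
    active = _active_norm(y) * f_scale
    passive = _passive_norm(y[6]) * f_scale
    total = active + passive
    if mode_clamp == 1:
        dsl = 0.0
    else:
        dsl = (load_kpa - total) / visc
        if y[6] >= sl0 and dsl > 0.0:
            dsl = 0.0
        if y[6] <= SL_MIN and dsl < 0.0:
            dsl = 0.0

    # mean distortions
    dxpr = dsl / 2.0 + (X_PSI / SS_XBPRER) * (
        -fappt * y[7] + hbt * (y[8] - X_0 - y[7])
    )
    dxpo = dsl / 2.0 + (X_PSI / SS_XBPOSTR) * hft * (y[7] + X_0 - y[8])

    y[0] += dt * dn
    y[1] += dt * dp
    y[2] += dt * dpre
    y[3] += dt * dpost
    y[4] += dt * dtl
    y[5] += dt * dth
    y[6] += dt * dsl
    y[7] += dt * dxpr
    y[8] += dt * dxpo
    return total


@njit(cache=False)
def _twitch_kernel(y, ca_grid_t, ca_grid_v, bcl_ms, n_beats, dt, mode_clamp,
                   load_kpa, sl0, visc, f_scale, record_stride):
    n_steps = int(round(bcl_ms * n_beats / dt))
    n_rec = n_steps // record_stride + 1
    t_out = np.empty(n_rec)
    tens_out = np.empty(n_rec)
    sl_out = np.empty(n_rec)
    atp_out = np.empty(n_rec)
    n_ca = ca_grid_t.shape[0]
    r = 0
    for s in range(n_steps):
        t = s * dt
        # periodic linear interpolation of the calcium transient
        tb = t % bcl_ms
        i = int(tb / bcl_ms * (n_ca - 1))
        # locate bracketing grid interval (grid may be non-uniform)
        while i < n_ca - 1 and ca_grid_t[i + 1] < tb:
            i += 1
        while i > 0 and ca_grid_t[i] > tb:
            i -= 1
        if i >= n_ca - 1:
            ca = ca_grid_v[n_ca - 1]
        else:
            w = (tb - ca_grid_t[i]) / (ca_grid_t[i + 1] - ca_grid_t[i])
            ca = ca_grid_v[i] * (1.0 - w) + ca_grid_v[i + 1] * w
        if s % record_stride == 0:
            sovf_thick, _ = _overlap(y[6])
            _, _, _, _, _, _, gxbt = _rates(y, ca)
            t_out[r] = t
            tens_out[r] = _active_norm(y) * f_scale
            sl_out[r] = y[6]
            atp_out[r] = gxbt * y[3] * sovf_thick
            r += 1
        _step_kernel(y, ca, dt, mode_clamp, load_kpa, sl0, visc, f_scale)
    return t_out[:r], tens_out[:r], sl_out[:r], atp_out[:r]


@dataclass
class TwitchResult:
    """Last-beat traces of a periodically driven twitch protocol.

    tension_kpa is the *active* tension; sl_trace is normalized by the
    initial (pre-shortening) muscle length; atp_rate is the raw detachment
    flux (1/ms, overlap-weighted) before normalization.
    """

    time_ms: np.ndarray
    tension_kpa: np.ndarray
    sl_trace: np.ndarray          # normalized length
    atp_rate: np.ndarray          # raw flux, 1/ms
    mode: str
    load_kpa: float
    sl0: float
    bcl_ms: float

    @property
    def peak_tension_kpa(self) -> float:
        return float(self.tension_kpa.max())

    @property
    def min_norm_length(self) -> float:
        return float(self.sl_trace.min())

    @property
    def peak_atp_rate(self) -> float:
        return float(self.atp_rate.max())


def step_xb(
    state: CrossBridgeState,
    ca_uM: float,
    dt: float = 0.02,
    mode: str = "isotonic",
    load_kpa: float = 1000.0,
    sl0: float | None = None,
    visc_kpa_ms_um: float = 50.0,
) -> CrossBridgeState:
    """Advance the cross-bridge ODEs one explicit step."""
    if dt > 0.1:
        raise InvalidParameterError("dt must be <= 0.1 ms")
    if ca_uM < 0:
        raise InvalidParameterError("ca_uM must be >= 0")
    if mode not in ("isotonic", "isometric"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    y = state.as_array()
    clamp = 1 if mode == "isometric" else 0
    _step_kernel(y, ca_uM, dt, clamp, load_kpa, sl0 if sl0 is not None else state.sl,
                 visc_kpa_ms_um, F_SCALE_KPA)
    if not np.all(np.isfinite(y)):
        raise NumericDomainError("cross-bridge state left the numeric domain")
    return CrossBridgeState.from_array(y)


def active_tension(state: CrossBridgeState) -> float:
    """Active tension (kPa): overlap-scaled, distortion-weighted attached fractions."""
    return float(_active_norm(state.as_array()) * F_SCALE_KPA)


def run_twitch(
    ct: CalciumTransient,
    mode: str = "isometric",
    load_kpa: float = 1000.0,
    sl0: float = 2.2,
    n_beats: int = 10,
    dt: float = 0.02,
    clamp: bool | None = None,
    record_every_ms: float = 0.5,
    visc_kpa_ms_um: float = 50.0,
) -> TwitchResult:
    """Drive the myofilament with a periodic calcium transient for ``n_beats``
    and return the last beat.

    ``mode='isometric'`` defaults to the high-afterload realization (the
    muscle never reaches the load so never shortens); pass ``clamp=True``
    for a hard length clamp instead.  ``mode='isotonic'`` shortens against
    ``load_kpa`` once active + passive tension exceeds it.
    """
    if mode not in ("isometric", "isotonic"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    if load_kpa <= 0:
        raise InvalidParameterError("load_kpa must be > 0")
    if clamp is None:
        clamp = False
    mode_clamp = 1 if (mode == "isometric" and clamp) else 0
    eff_load = load_kpa if mode == "isotonic" else max(load_kpa, 1000.0)
    y = init_xb_state(sl0).as_array()
    stride = max(1, int(round(record_every_ms / dt)))
    t, tens, sl, atp = _twitch_kernel(
        y, ct.time_ms, ct.ca_uM, ct.bcl_ms, n_beats, dt, mode_clamp,
        eff_load, sl0, visc_kpa_ms_um, F_SCALE_KPA, stride,
    )
    if not (np.all(np.isfinite(tens)) and np.all(np.isfinite(sl))):
        raise NumericDomainError("twitch integration left the numeric domain")
    # keep the final beat only (steady cycling)
    t0 = (n_beats - 1) * ct.bcl_ms
    msk = t >= t0 - 1e-9
    return TwitchResult(
        time_ms=t[msk] - t0,
        tension_kpa=tens[msk],
        sl_trace=sl[msk] / sl0,
        atp_rate=atp[msk],
        mode=mode,
        load_kpa=load_kpa,
        sl0=sl0,
        bcl_ms=ct.bcl_ms,
    )


def atp_consumption(result: TwitchResult, normalizing_peak: float) -> np.ndarray:
    """ATP rate trace normalized by a reference peak (the normal-isometric peak)."""
    if normalizing_peak <= 0:
        raise InvalidParameterError("normalizing_peak must be > 0")
    return result.atp_rate / normalizing_peak


def steady_state_force_ca(sl: float, ca_grid_uM: np.ndarray) -> np.ndarray:
    """Steady-state active tension (kPa) at each fixed calcium level.

    Algebraic solve: troponin occupancies equilibrate, the permissivity
    switch fixes the N<->P rates, and the attached fractions follow from the
    linear rate balance of the four-state chain at steady-state distortions
    (x_prer = 0, x_postr = x_0, where the strain modulations are unity).
    Serves as the independent oracle for the time-marched `step_xb`.
    """
    ca_grid_uM = np.asarray(ca_grid_uM, dtype=float)
    if np.any(ca_grid_uM < 0) or np.any(np.diff(ca_grid_uM) <= 0):
        raise InvalidParameterError("ca grid must be nonnegative and increasing")
    if not (SL_MIN <= sl <= SL_MAX):
        raise InvalidParameterError(f"sl = {sl} outside [{SL_MIN}, {SL_MAX}] µm")
    sovf_thick, sovf_thin = _overlap(sl)
    out = np.empty_like(ca_grid_uM)
    for k, ca in enumerate(ca_grid_uM):
        tl = KON * ca / (KON * ca + KOFF_L) if ca > 0 else 0.0
        th = KON * ca / (KON * ca + KOFF_H) if ca > 0 else 0.0
        trop_reg = max((1.0 - sovf_thin) * tl + sovf_thin * th, 1e-12)
        permtot = math.sqrt(1.0 / (1.0 + (PERM50 / trop_reg) ** NPERM))
        kn_pt = KN_P * permtot
        kp_nt = KP_N * min(1.0 / permtot, 100.0)
        gappt = GAPP * (1.0 + (1.0 - sovf_thick) * GSLMOD)
        # linear chain steady state (unit P, then renormalize)
        x2_of_x1 = HF_R / (HB_R + GXB)
        x1 = FAPP * (HB_R + GXB) / ((gappt + HF_R) * (HB_R + GXB) - HB_R * HF_R)
        x2 = x2_of_x1 * x1
        n_of_p = kp_nt / kn_pt
        total = n_of_p + 1.0 + x1 + x2
        xb_postr = x2 / total
        out[k] = sovf_thick * (X_0 * xb_postr) / (X_0 * SS_XBPOSTR) * F_SCALE_KPA
    return out
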
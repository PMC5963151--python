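"""Closed-loop lumped cardiovascular model with a continuous-flow LVAD.

Network (single loop):

    LV -[AO valve]-> SA -(RSA)-> SV -(RSV)-> RA -[TR valve]-> RV
       -[PU valve]-> PA -(RPA)-> PV -(RPV)-> LA -[MI valve]-> LV

with an optional LVAD drawing a constant flow from the LV and delivering it
to the systemic artery (SA).  Atria and vessels are passive compliances
(P = V/C on stressed volume); valves are ideal diodes realized with a
narrow softplus smoothing so the system stays smooth for fixed-step
integration.  The ventricles are 0D surrogates blending an end-systolic
elastance line with an exponential end-diastolic relation:

    P(V, a) = a * E_es * (V - V0) + (1 - a) * A * (expm1(B * (V - V0)))

where the activation a(t) in [0, 1] is the myofilament active tension of
the current condition's calcium transient normalized by a per-ventricle
reference tension (clipped to [0, 1]).  Heart failure weakens a(t) through
the remodeled calcium transient; the LVAD scenario adds the pump at its set
flow.  Simulation: fixed-step RK4 (default dt 0.25 ms), which conserves the
closed-loop blood volume to round-off because every flow appears once as a
source and once as a sink.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from .calcium import TransientParams, apply_hf_remodeling, make_transient
from .exceptions import CalibrationError, InvalidParameterError
from .myofilament import run_twitch

__all__ = [
    "CirculationParams",
    "VentricleSurrogateParams",
    "ScenarioResult",
    "ventricle_pressure",
    "valve_flow",
    "lvad_flow",
    "run_scenario",
    "simulate",
    "calibrate_normal",
    "load_default_params",
    "activation_from_transient",
    "CONDITIONS",
]

CONDITIONS = ("normal", "hf", "hf_lvad")

_SMOOTH_W = 0.01  # mmHg, diode smoothing width


@dataclass(frozen=True)
class VentricleSurrogateParams:
    """0D ventricle: ESPVR slope e_es (mmHg/mL), unstressed volume v0 (mL),
    EDPVR scale edp_a (mmHg) and exponent edp_b (1/mL), and the tension
    normalization t_act_ref (kPa) mapping myofilament tension to activation."""

    e_es: float
    v0: float
    edp_a: float
    edp_b: float
    t_act_ref: float
    act_exponent: float = 2.0

    def __post_init__(self) -> None:
        if self.act_exponent <= 0:
            raise InvalidParameterError("act_exponent must be > 0")
        if self.e_es <= 0:
            raise InvalidParameterError("e_es must be > 0")
        if self.v0 < 0:
            raise InvalidParameterError("v0 must be >= 0")
        for name in ("edp_a", "edp_b", "t_act_ref"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")


@dataclass(frozen=True)
class CirculationParams:
    """Resistances (mmHg·s/mL), compliances (mL/mmHg), total stressed blood
    volume (mL), LVAD set flow (L/min) and the two ventricle surrogates."""

    r_mi: float
    r_ao: float
    r_sa: float
    r_sv: float
    r_tr: float
    r_pu: float
    r_pa: float
    r_pv: float
    c_la: float
    c_sa: float
    c_sv: float
    c_ra: float
    c_pa: float
    c_pv: float
    total_volume_ml: float
    lvad_flow_lpm: float
    lv: VentricleSurrogateParams
    rv: VentricleSurrogateParams

    def __post_init__(self) -> None:
        for name in ("r_mi", "r_ao", "r_sa", "r_sv", "r_tr", "r_pu", "r_pa", "r_pv",
                     "c_la", "c_sa", "c_sv", "c_ra", "c_pa", "c_pv", "total_volume_ml"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.lvad_flow_lpm < 0:
            raise InvalidParameterError("lvad_flow_lpm must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CirculationParams":
        d = dict(d)
        d["lv"] = VentricleSurrogateParams(**d["lv"])
        d["rv"] = VentricleSurrogateParams(**d["rv"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CirculationParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


def load_default_params() -> CirculationParams:
    """The package's canonical normal-condition parameter set.

    Obtained by `calibrate_normal` against normal-condition hemodynamic
    targets and frozen into the packaged JSON file.
    """
    with resources.files("cardioem.params").joinpath("circulation_normal.json").open() as fh:
        return CirculationParams.from_dict(json.load(fh))


def ventricle_pressure(v: float, a: float, p: VentricleSurrogateParams) -> float:
    """Surrogate ventricular pressure (mmHg) at volume v and activation a.

    The normalized-tension activation is sharpened by a cooperative exponent
    (a_eff = a**act_exponent) before blending the ESPVR and EDPVR limbs:
    chamber pressure generation falls off faster than myofilament tension
    when activation is submaximal, which stands in for the length- and
    geometry-dependent losses of a deforming ventricle.
    """
    if not (0.0 <= a <= 1.0):
        raise InvalidParameterError("activation a must lie in [0, 1]")
    a_eff = a ** p.act_exponent
    p_es = p.e_es * (v - p.v0)
    p_ed = p.edp_a * math.expm1(p.edp_b * (v - p.v0))
    return a_eff * p_es + (1.0 - a_eff) * p_ed


def valve_flow(p_up: float, p_down: float, r: float) -> float:
    """Ideal-diode valve flow (mL/s): max(0, dP)/r, no regurgitation."""
    if r <= 0:
        raise InvalidParameterError("valve resistance must be > 0")
    return max(0.0, p_up - p_down) / r


def lvad_flow(t_ms: float, params: CirculationParams) -> float:
    """Constant pump flow (mL/s) from LV to aorta; time-independent."""
    return params.lvad_flow_lpm * 1000.0 / 60.0


# state layout: [V_LA, V_LV, V_RA, V_RV, V_SA, V_SV, V_PA, V_PV]
_ILA, _ILV, _IRA, _IRV, _ISA, _ISV, _IPA, _IPV = range(8)


@njit(cache=False)
def _diode(dp: float, r: float, w: float) -> float:
    # softplus-smoothed diode; exact in both limits
    x = dp / w
    if x > 30.0:
        return dp / r
    if x < -30.0:
        return 0.0
    return w * np.log1p(np.exp(x)) / r

@njit(cache=False)
def _vent_p(v, a, e_es, v0, edp_a, edp_b, n_act):
    ae = a ** n_act
    return ae * e_es * (v - v0) + (1.0 - ae) * edp_a * (np.expm1(edp_b * (v - v0)))


@njit(cache=False)
def _derivs(vol, a_lv, a_rv, pars, q_lvad, out, flows):
    """Volume ODE right-hand side; flows in mL/s, volumes mL, dV/dt in mL/s."""
    (r_mi, r_ao, r_sa, r_sv, r_tr, r_pu, r_pa, r_pv,
     c_la, c_sa, c_sv, c_ra, c_pa, c_pv,
     lv_ees, lv_v0, lv_a, lv_b, lv_n, rv_ees, rv_v0, rv_a, rv_b, rv_n) = pars

    p_la = vol[_ILA] / c_la
    p_sa = vol[_ISA] / c_sa
    p_sv = vol[_ISV] / c_sv
    p_ra = vol[_IRA] / c_ra
    p_pa = vol[_IPA] / c_pa
    p_pv = vol[_IPV] / c_pv
    p_lv = _vent_p(vol[_ILV], a_lv, lv_ees, lv_v0, lv_a, lv_b, lv_n)
    p_rv = _vent_p(vol[_IRV], a_rv, rv_ees, rv_v0, rv_a, rv_b, rv_n)

    # pump suction limit: the set flow tapers smoothly when the LV is nearly
    # empty (below ~12 mL) so the flow generator cannot draw negative volume
    if q_lvad > 0.0:
        xs = (vol[_ILV] - 12.0) / 2.0
        if xs < -30.0:
            q_lvad = 0.0
        elif xs < 30.0:
            q_lvad = q_lvad / (1.0 + np.exp(-xs))

    q_mi = _diode(p_la - p_lv, r_mi, _SMOOTH_W)
    q_ao = _diode(p_lv - p_sa, r_ao, _SMOOTH_W)
    q_sa = (p_sa - p_sv) / r_sa
    q_sv = (p_sv - p_ra) / r_sv
    q_tr = _diode(p_ra - p_rv, r_tr, _SMOOTH_W)
    q_pu = _diode(p_rv - p_pa, r_pu, _SMOOTH_W)
    q_pa = (p_pa - p_pv) / r_pa
    q_pv = (p_pv - p_la) / r_pv

    out[_ILA] = q_pv - q_mi
    out[_ILV] = q_mi - q_ao - q_lvad
    out[_IRA] = q_sv - q_tr
    out[_IRV] = q_tr - q_pu
    out[_ISA] = q_ao + q_lvad - q_sa
    out[_ISV] = q_sa - q_sv
    out[_IPA] = q_pu - q_pa
    out[_IPV] = q_pa - q_pv

    flows[0] = q_mi
    flows[1] = q_ao
    flows[2] = q_tr
    flows[3] = q_pu
    flows[4] = q_lvad
    flows[5] = p_lv
    flows[6] = p_rv
    flows[7] = p_la
    flows[8] = p_ra
    flows[9] = p_sa
    flows[10] = p_pa
    flows[11] = p_sv
    flows[12] = p_pv


@njit(cache=False)
def _act_lookup(t_ms, act, act_dt, bcl_ms):
    tb = t_ms % bcl_ms
    x = tb / act_dt
    i = int(x)
    n = act.shape[0]
    if i >= n - 1:
        # wrap the final interval to the start of the next beat
        w = x - i
        return act[n - 1] * (1.0 - w) + act[0] * w
    w = x - i
    return act[i] * (1.0 - w) + act[i + 1] * w


@njit(cache=False)
def _run_kernel(vol0, pars, act_lv, act_rv, act_dt, bcl_ms, q_lvad,
                n_cycles, dt_ms, record_stride):
    n_steps = int(round(n_cycles * bcl_ms / dt_ms))
    n_rec = n_steps // record_stride + 1
    rec = np.empty((n_rec, 1 + 8 + 13))  # time, volumes, flows/pressures
    vol = vol0.copy()
    k1 = np.empty(8); k2 = np.empty(8); k3 = np.empty(8); k4 = np.empty(8)
    flows = np.empty(13)
    tmp = np.empty(8)
    dt_s = dt_ms / 1000.0
    r = 0
    for s in range(n_steps):
        t = s * dt_ms
        a_lv = _act_lookup(t, act_lv, act_dt, bcl_ms)
        a_rv = _act_lookup(t, act_rv, act_dt, bcl_ms)
        if s % record_stride == 0:
            _derivs(vol, a_lv, a_rv, pars, q_lvad, k1, flows)
            rec[r, 0] = t
            for i in range(8):
                rec[r, 1 + i] = vol[i]
            for i in range(13):
                rec[r, 9 + i] = flows[i]
            r += 1
        # RK4 on the volume ODEs (activation held over substeps at midpoints)
        a_lv_h = _act_lookup(t + dt_ms / 2.0, act_lv, act_dt, bcl_ms)
        a_rv_h = _act_lookup(t + dt_ms / 2.0, act_rv, act_dt, bcl_ms)
        a_lv_f = _act_lookup(t + dt_ms, act_lv, act_dt, bcl_ms)
        a_rv_f = _act_lookup(t + dt_ms, act_rv, act_dt, bcl_ms)
        _derivs(vol, a_lv, a_rv, pars, q_lvad, k1, flows)
        for i in range(8):
            tmp[i] = vol[i] + 0.5 * dt_s * k1[i]
        _derivs(tmp, a_lv_h, a_rv_h, pars, q_lvad, k2, flows)
        for i in range(8):
            tmp[i] = vol[i] + 0.5 * dt_s * k2[i]
        _derivs(tmp, a_lv_h, a_rv_h, pars, q_lvad, k3, flows)
        for i in range(8):
            tmp[i] = vol[i] + dt_s * k3[i]
        _derivs(tmp, a_lv_f, a_rv_f, pars, q_lvad, k4, flows)
        for i in range(8):
            vol[i] += dt_s / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
    t = n_steps * dt_ms
    a_lv = _act_lookup(t, act_lv, act_dt, bcl_ms)
    a_rv = _act_lookup(t, act_rv, act_dt, bcl_ms)
    _derivs(vol, a_lv, a_rv, pars, q_lvad, k1, flows)
    rec[r, 0] = t
    for i in range(8):
        rec[r, 1 + i] = vol[i]
    for i in range(13):
        rec[r, 9 + i] = flows[i]
    return rec[: r + 1]


_COLUMNS = [
    "time_ms",
    "v_la", "v_lv", "v_ra", "v_rv", "v_sa", "v_sv", "v_pa", "v_pv",
    "q_mi", "q_ao", "q_tr", "q_pu", "q_lvad",
    "p_lv", "p_rv", "p_la", "p_ra", "p_ao", "p_pa", "p_sv", "p_pv",
]


@dataclass
class ScenarioResult:
    """Beat-resolved traces of one scenario plus bookkeeping."""

    traces: pd.DataFrame
    condition: str
    params: CirculationParams
    bcl_ms: float
    n_cycles: int
    steady_state_metric: float    # relative last-two-beat EDV change (LV)
    activation_lv: np.ndarray
    activation_rv: np.ndarray

    def last_beat(self) -> pd.DataFrame:
        from .hemodynamics import segment_last_beat
        return segment_last_beat(self.traces, self.bcl_ms)


def _pack_pars(p: CirculationParams) -> np.ndarray:
    return np.array([
        p.r_mi, p.r_ao, p.r_sa, p.r_sv, p.r_tr, p.r_pu, p.r_pa, p.r_pv,
        p.c_la, p.c_sa, p.c_sv, p.c_ra, p.c_pa, p.c_pv,
        p.lv.e_es, p.lv.v0, p.lv.edp_a, p.lv.edp_b, p.lv.act_exponent,
        p.rv.e_es, p.rv.v0, p.rv.edp_a, p.rv.edp_b, p.rv.act_exponent,
    ])


def _initial_volumes(p: CirculationParams) -> np.ndarray:
    # distribute the stressed volume with most in the venous beds
    frac = np.array([0.05, 0.20, 0.05, 0.20, 0.18, 0.14, 0.06, 0.12])
    frac = frac / frac.sum()
    return frac * p.total_volume_ml


from functools import lru_cache


@lru_cache(maxsize=16)
def _isometric_tension_cached(
    params: TransientParams, sl0: float, n_beats: int, record_every_ms: float
) -> tuple[np.ndarray, float]:
    ct = make_transient(params, dt=1.0)
    tw = run_twitch(ct, mode="isometric", n_beats=n_beats,
                    record_every_ms=record_every_ms, sl0=sl0)
    tens = tw.tension_kpa
    tens.setflags(write=False)
    return tens, float(tw.time_ms[1] - tw.time_ms[0])


def activation_from_transient(
    params: TransientParams,
    t_act_ref: float,
    sl0: float = 2.2,
    n_beats: int = 10,
    record_every_ms: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Normalized activation waveform a(t) over one beat from an isometric twitch.

    Runs the myofilament model under the transient, takes the last-beat
    active-tension trace, divides by ``t_act_ref`` and clips to [0, 1].
    Returns (activation samples on a uniform grid, grid step ms).  The
    underlying twitch is cached per transient, so varying ``t_act_ref`` is
    cheap.
    """
    tens, dt_act = _isometric_tension_cached(params, sl0, n_beats, record_every_ms)
    act = np.clip(tens / t_act_ref, 0.0, 1.0)
    return act, dt_act


def simulate(
    params: CirculationParams,
    act_lv: np.ndarray,
    act_rv: np.ndarray,
    act_dt_ms: float,
    bcl_ms: float = 800.0,
    n_cycles: int = 25,
    dt_ms: float = 0.25,
    record_every_ms: float = 1.0,
    initial_volumes: np.ndarray | None = None,
) -> pd.DataFrame:
    """Integrate the closed loop for ``n_cycles`` beats; returns the trace table."""
    if dt_ms > 1.0:
        raise InvalidParameterError("dt_ms must be <= 1 ms for the explicit scheme")
    vol0 = _initial_volumes(params) if initial_volumes is None else np.asarray(initial_volumes, float)
    rec = _run_kernel(
        vol0, _pack_pars(params), np.asarray(act_lv, float), np.asarray(act_rv, float),
        act_dt_ms, bcl_ms, params.lvad_flow_lpm * 1000.0 / 60.0,
        n_cycles, dt_ms, max(1, int(round(record_every_ms / dt_ms))),
    )
    df = pd.DataFrame(
        rec,
        columns=["time_ms",
                 "v_la", "v_lv", "v_ra", "v_rv", "v_sa", "v_sv", "v_pa", "v_pv",
                 "q_mi", "q_ao", "q_tr", "q_pu", "q_lvad",
                 "p_lv", "p_rv", "p_la", "p_ra", "p_ao", "p_pa", "p_sv", "p_pv"],
    )
    if (df[["v_la", "v_lv", "v_ra", "v_rv", "v_sa", "v_sv", "v_pa", "v_pv"]].to_numpy() < 0).any():
        raise InvalidParameterError(
            "a compartment volume went negative; reduce dt or revisit parameters"
        )
    return df


def run_scenario(
    condition: str = "normal",
    n_cycles: int = 25,
    bcl_ms: float = 800.0,
    params: CirculationParams | None = None,
    transient: TransientParams | None = None,
    hf_amp_factor: float = 0.7,
    hf_tau_factor: float = 0.7,
    lvad_flow_lpm: float = 4.0,
    dt_ms: float = 0.25,
) -> ScenarioResult:
    """Run one of the three study conditions to (approximate) steady state.

    normal: normal calcium transient, pump off; hf: remodeled transient
    (amplitude x0.7, decay time constant x0.7), pump off; hf_lvad: remodeled
    transient with the pump at its set flow (default 4 L/min).
    """
    if condition not in CONDITIONS:
        raise InvalidParameterError(f"condition must be one of {CONDITIONS}")
    if params is None:
        params = load_default_params()
    base = transient if transient is not None else TransientParams(bcl_ms=bcl_ms)
    if condition == "normal":
        tp = base
        params = replace(params, lvad_flow_lpm=0.0)
    else:
        tp = apply_hf_remodeling(base, hf_amp_factor, hf_tau_factor)
        params = replace(
            params, lvad_flow_lpm=lvad_flow_lpm if condition == "hf_lvad" else 0.0
        )
    act_lv, dt_act = activation_from_transient(tp, params.lv.t_act_ref)
    act_rv, _ = activation_from_transient(tp, params.rv.t_act_ref)
    traces = simulate(params, act_lv, act_rv, dt_act, bcl_ms, n_cycles, dt_ms)

    # steady-state metric: relative change of LV EDV over the last two beats
    t = traces["time_ms"].to_numpy()
    v = traces["v_lv"].to_numpy()
    last = v[(t >= (n_cycles - 1) * bcl_ms)]
    prev = v[(t >= (n_cycles - 2) * bcl_ms) & (t < (n_cycles - 1) * bcl_ms)]
    metric = abs(last.max() - prev.max()) / last.max()
    if metric > 0.01:
        import warnings
        warnings.warn(
            f"steady state not attained: last-two-beat EDV change {metric:.2%}",
            stacklevel=2,
        )
    return ScenarioResult(
        traces=traces, condition=condition, params=params, bcl_ms=bcl_ms,
        n_cycles=n_cycles, steady_state_metric=float(metric),
        activation_lv=act_lv, activation_rv=act_rv,
    )


_DEFAULT_TARGETS = {
    "lvesp": 110.0, "lvedv": 112.0, "lvesv": 61.0, "lvco": 3.8,
    "lvedp": 5.0, "rvesp": 16.0, "rvedv": 136.0, "raesp": 4.0, "paesp": 13.0,
}

_FREE_PARAM_SPECS = {
    # name -> (getter path, lower bound, upper bound)
    "lv_e_es": (1.0, 5.0),
    "lv_v0": (0.0, 30.0),
    "lv_edp_b": (0.01, 0.08),
    "rv_e_es": (0.1, 1.5),
    "rv_v0": (0.0, 60.0),
    "rv_edp_b": (0.005, 0.06),
    "r_sa": (0.5, 3.0),
    "r_pa": (0.02, 0.5),
    "c_sa": (0.5, 3.0),
    "c_pa": (1.0, 15.0),
    "total_volume_ml": (300.0, 900.0),
}


def _apply_free(params: CirculationParams, names: list[str], x: np.ndarray) -> CirculationParams:
    d = params.to_dict()
    for name, val in zip(names, x):
        if name.startswith("lv_"):
            d["lv"][name[3:]] = float(val)
        elif name.startswith("rv_"):
            d["rv"][name[3:]] = float(val)
        else:
            d[name] = float(val)
    return CirculationParams.from_dict(d)


def calibrate_normal(
    targets: dict[str, float] | None = None,
    free: list[str] | None = None,
    base_params: CirculationParams | None = None,
    n_cycles: int = 15,
    residual_threshold: float = 0.2,
    verbose: bool = False,
) -> tuple[CirculationParams, dict[str, float]]:
    """Bounded least-squares fit of circulation parameters to normal targets.

    Targets are relative-error residuals on the normal-condition hemodynamic
    summary.  Returns (fitted params, residual report).  Raises
    CalibrationError when the worst relative residual exceeds
    ``residual_threshold``.
    """
    from scipy.optimize import least_squares
    from .hemodynamics import segment_last_beat, summarize_beat

    targets = dict(_DEFAULT_TARGETS if targets is None else targets)
    if free is None:
        free = list(_FREE_PARAM_SPECS)
    for name in free:
        if name not in _FREE_PARAM_SPECS:
            raise InvalidParameterError(f"unknown free parameter {name!r}")
    params0 = load_default_params() if base_params is None else base_params
    d0 = params0.to_dict()

    def get0(name):
        if name.startswith("lv_"):
            return d0["lv"][name[3:]]
        if name.startswith("rv_"):
            return d0["rv"][name[3:]]
        return d0[name]

    x0 = np.array([get0(n) for n in free])
    lb = np.array([_FREE_PARAM_SPECS[n][0] for n in free])
    ub = np.array([_FREE_PARAM_SPECS[n][1] for n in free])
    x0 = np.clip(x0, lb, ub)

    def residuals(x):
        p = _apply_free(params0, free, x)
        try:
            res = run_scenario("normal", n_cycles=n_cycles, params=p)
        except InvalidParameterError:
            return np.full(len(targets), 10.0)
        beat = segment_last_beat(res.traces, res.bcl_ms)
        summ = summarize_beat(beat, res.bcl_ms).as_dict()
        out = np.array([(summ[k] - v) / abs(v) for k, v in targets.items()])
        if verbose:
            print({k: round(summ[k], 2) for k in targets}, "->", np.abs(out).max())
        return out

    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol = least_squares(residuals, x0, bounds=(lb, ub), diff_step=0.05,
                            xtol=1e-4, ftol=1e-4, max_nfev=60)
    fitted = _apply_free(params0, free, sol.x)
    report = {k: float(r) for k, r in zip(targets, sol.fun)}
    worst = max(abs(v) for v in report.values())
    if worst > residual_threshold:
        worst_keys = sorted(report, key=lambda k: -abs(report[k]))[:3]
        raise CalibrationError(
            f"calibration residual {worst:.2f} exceeds {residual_threshold}; "
            f"worst targets: {worst_keys}"
        )
    return fitted, report
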
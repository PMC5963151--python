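"""Pressure-volume loop analysis: beat segmentation, hemodynamic summaries,
condition-to-condition percent changes, and synthetic PV fixtures.

Conventions
-----------
* End-diastolic volume (EDV) is the beat maximum of ventricular volume and
  end-systolic volume (ESV) the minimum.
* End-systolic pressure (ESP) defaults to the peak ventricular pressure over
  the beat (the systolic peak of the pressure trace); a ``pressure at ESV``
  mode is available behind ``esp_mode="at_esv"``.
* Stroke work (SW) is the magnitude of the PV-loop area, |∮ P dV|, by the
  shoelace rule on the closed loop.
* Negative end-diastolic pressures are legal (pressures below atmospheric).
* Cardiac output uses the pacing period: CO = SV * (60000 / bcl_ms) / 1000
  L/min.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError, InvalidParameterError

__all__ = [
    "VentricleSummary",
    "HemodynamicSummary",
    "ComparisonRow",
    "segment_last_beat",
    "summarize_beat",
    "summarize_pv",
    "percent_change",
    "compare_conditions",
    "isovolumetric_phases",
    "valve_open_durations",
    "synth_pv_fixture",
    "TABLE_QUANTITIES",
]

#: Quantity names in report (row) order, mirroring the standard LV/RV table.
TABLE_QUANTITIES = [
    "lvesp", "lvedp", "lvpp", "raesp", "rvesp", "rvedp", "paesp", "rvpp",
    "lvco", "lvedv", "lvesv", "lvsv", "lvef", "lvsw",
    "rvco", "rvedv", "rvesv", "rvsv", "rvef", "rvsw",
]


@dataclass(frozen=True)
class VentricleSummary:
    """Single-ventricle beat summary.

    Pressures in mmHg, volumes in mL, ef in %, co in L/min, sw in mmHg*mL.
    """

    esp: float
    edp: float
    edv: float
    esv: float
    sw: float
    bcl_ms: float

    @property
    def pp(self) -> float:
        return self.esp - self.edp

    @property
    def sv(self) -> float:
        return self.edv - self.esv

    @property
    def ef(self) -> float:
        return 100.0 * self.sv / self.edv

    @property
    def co(self) -> float:
        return self.sv * (60000.0 / self.bcl_ms) / 1000.0


@dataclass(frozen=True)
class HemodynamicSummary:
    """The full per-condition row set: both ventricles plus RA/PA peaks."""

    lv: VentricleSummary
    rv: VentricleSummary
    raesp: float
    paesp: float

    def as_dict(self) -> dict[str, float]:
        return {
            "lvesp": self.lv.esp, "lvedp": self.lv.edp, "lvpp": self.lv.pp,
            "raesp": self.raesp, "rvesp": self.rv.esp, "rvedp": self.rv.edp,
            "paesp": self.paesp, "rvpp": self.rv.pp,
            "lvco": self.lv.co, "lvedv": self.lv.edv, "lvesv": self.lv.esv,
            "lvsv": self.lv.sv, "lvef": self.lv.ef, "lvsw": self.lv.sw,
            "rvco": self.rv.co, "rvedv": self.rv.edv, "rvesv": self.rv.esv,
            "rvsv": self.rv.sv, "rvef": self.rv.ef, "rvsw": self.rv.sw,
        }

    def as_series(self) -> pd.Series:
        return pd.Series(self.as_dict()).reindex(TABLE_QUANTITIES)


@dataclass(frozen=True)
class ComparisonRow:
    quantity: str
    baseline: float
    new: float

    @property
    def percent_change(self) -> float:
        return percent_change(self.baseline, self.new)


def segment_last_beat(traces: pd.DataFrame, bcl_ms: float, align_col: str | None = None) -> pd.DataFrame:
    """Slice the final full cycle of a multi-beat trace table.

    ``traces`` must have a ``time_ms`` column spanning at least two cycles.
    When ``align_col`` is given (e.g. an activation trace), the window is
    aligned to the minimum of that column within the final beat; otherwise
    the final ``bcl_ms`` window of the trace is returned.
    """
    t = traces["time_ms"].to_numpy()
    dt = t[1] - t[0]
    if t[-1] - t[0] < 2 * bcl_ms - 2 * dt - 1e-9:
        raise InsufficientDataError(
            f"trace spans {t[-1] - t[0]:.1f} ms, need at least two cycles ({2 * bcl_ms:.0f} ms)"
        )
    t_end = t[-1]
    start = t_end - bcl_ms
    if align_col is not None:
        window = traces[(t >= t_end - 2 * bcl_ms) & (t <= t_end - bcl_ms)]
        i_min = window[align_col].to_numpy().argmin()
        start = window["time_ms"].to_numpy()[i_min]
    out = traces[(traces["time_ms"] >= start - 1e-9) & (traces["time_ms"] < start + bcl_ms - 1e-9)]
    return out.reset_index(drop=True)


def _loop_area(p: np.ndarray, v: np.ndarray) -> float:
    """|∮ P dV| by the shoelace rule; the loop is closed by returning to the start."""
    pc = np.append(p, p[0])
    vc = np.append(v, v[0])
    return abs(float(np.sum(0.5 * (pc[1:] + pc[:-1]) * np.diff(vc))))


def summarize_pv(
    p: np.ndarray, v: np.ndarray, bcl_ms: float, esp_mode: str = "peak"
) -> VentricleSummary:
    """Summarize one beat of a single ventricle's pressure/volume traces."""
    p = np.asarray(p, dtype=float)
    v = np.asarray(v, dtype=float)
    if p.shape != v.shape or p.ndim != 1 or p.size < 4:
        raise InvalidParameterError("p and v must be congruent 1-D arrays with >= 4 samples")
    edv = float(v.max())
    esv = float(v.min())
    edp = float(p[int(v.argmax())])
    if esp_mode == "peak":
        esp = float(p.max())
    elif esp_mode == "at_esv":
        esp = float(p[int(v.argmin())])
    else:
        raise InvalidParameterError(f"unknown esp_mode {esp_mode!r}")
    sw = _loop_area(p, v)
    return VentricleSummary(esp=esp, edp=edp, edv=edv, esv=esv, sw=sw, bcl_ms=bcl_ms)


def summarize_beat(beat: pd.DataFrame, bcl_ms: float, esp_mode: str = "peak") -> HemodynamicSummary:
    """Summarize a one-beat slice holding both ventricles plus RA and PA pressures.

    Required columns: p_lv, v_lv, p_rv, v_rv, p_ra, p_pa.
    """
    lv = summarize_pv(beat["p_lv"].to_numpy(), beat["v_lv"].to_numpy(), bcl_ms, esp_mode)
    rv = summarize_pv(beat["p_rv"].to_numpy(), beat["v_rv"].to_numpy(), bcl_ms, esp_mode)
    return HemodynamicSummary(
        lv=lv,
        rv=rv,
        raesp=float(beat["p_ra"].max()),
        paesp=float(beat["p_pa"].max()),
    )


def percent_change(baseline: float, new: float) -> float:
    """Signed percent change 100*(new - baseline)/baseline."""
    if baseline == 0:
        raise InvalidParameterError("percent change undefined for zero baseline")
    return 100.0 * (new - baseline) / baseline


def compare_conditions(
    summaries: Mapping[str, HemodynamicSummary],
    pairs: Sequence[tuple[str, str]] = (("normal", "hf"), ("hf", "hf_lvad")),
    quantities: Sequence[str] = tuple(TABLE_QUANTITIES),
) -> pd.DataFrame:
    """Percent-change table: one row per (quantity, condition pair)."""
    rows = []
    for base_name, new_name in pairs:
        for name in (base_name, new_name):
            if name not in summaries:
                raise KeyError(f"condition {name!r} missing from summaries")
        base = summaries[base_name].as_dict()
        new = summaries[new_name].as_dict()
        for q in quantities:
            rows.append(
                {
                    "quantity": q,
                    "pair": f"{base_name}->{new_name}",
                    "baseline": base[q],
                    "new": new[q],
                    "percent_change": percent_change(base[q], new[q]) if base[q] != 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def isovolumetric_phases(
    beat: pd.DataFrame,
    volume_col: str = "v_lv",
    pressure_col: str = "p_lv",
    dv_threshold_ml_per_10ms: float = 0.5,
    min_duration_ms: float = 20.0,
    min_pressure_change_mmhg: float = 5.0,
) -> list[tuple[float, float]]:
    """Intervals where ventricular volume is constant while pressure swings.

    A sample belongs to a candidate interval when |dV/dt| < threshold
    (expressed as mL per 10 ms).  Candidates shorter than
    ``min_duration_ms`` or with a pressure excursion below
    ``min_pressure_change_mmhg`` are discarded.

    The default threshold (0.5 mL per 10 ms) deliberately lies below the
    drain rate of a 4 L/min continuous pump (0.67 mL per 10 ms), so a
    valve-closed segment with the pump running — pressure swinging while
    volume ramps down — is classified as *not* isovolumetric, while a true
    both-valves-closed segment (volume flat to numerical precision) is.
    """
    if dv_threshold_ml_per_10ms <= 0:
        raise InvalidParameterError("dv threshold must be > 0")
    t = beat["time_ms"].to_numpy()
    v = beat[volume_col].to_numpy()
    p = beat[pressure_col].to_numpy()
    dvdt = np.gradient(v, t) * 10.0  # mL per 10 ms
    flat = np.abs(dvdt) < dv_threshold_ml_per_10ms
    phases: list[tuple[float, float]] = []
    i = 0
    n = len(t)
    while i < n:
        if flat[i]:
            j = i
            while j + 1 < n and flat[j + 1]:
                j += 1
            if t[j] - t[i] >= min_duration_ms and np.ptp(p[i : j + 1]) > min_pressure_change_mmhg:
                phases.append((float(t[i]), float(t[j])))
            i = j + 1
        else:
            i += 1
    return phases


def valve_open_durations(
    beat: pd.DataFrame,
    flow_cols: Sequence[str] = ("q_mi", "q_ao", "q_tr", "q_pu"),
    rel_threshold: float = 0.1,
) -> dict[str, float]:
    """Per-valve opening duration (ms) within one beat.

    A valve counts as open while its flow exceeds ``rel_threshold`` times its
    beat peak — the conventional way a flow wave is delimited, robust to the
    small leakage scale of smoothed diodes.  A valve that never flows gets 0.
    """
    t = beat["time_ms"].to_numpy()
    dt = float(np.median(np.diff(t)))
    out = {}
    for col in flow_cols:
        q = beat[col].to_numpy()
        pk = q.max()
        out[col] = float((q > rel_threshold * pk).sum()) * dt if pk > 0 else 0.0
    return out


def synth_pv_fixture(
    esp: float,
    edp: float,
    edv: float,
    esv: float,
    bcl_ms: float = 800.0,
    n_samples: int = 800,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic one-beat ventricular PV loop hitting prescribed extremes exactly.

    Builds a smooth four-phase loop — filling (EDP/EDV corner), isovolumetric
    contraction at EDV, ejection down to ESV at peak pressure ESP,
    isovolumetric relaxation at ESV — sampled on ``n_samples`` points.
    ``edp`` may be negative.  Optional seeded Gaussian noise perturbs interior
    samples only, so the prescribed extremes survive.
    """
    if edv <= esv:
        raise InvalidParameterError(f"EDV ({edv}) must exceed ESV ({esv})")
    if n_samples < 40:
        raise InvalidParameterError("n_samples too small for a four-phase loop")
    t = np.linspace(0.0, bcl_ms, n_samples, endpoint=False)
    # phase boundaries as fractions of the cycle
    f_ivc, f_ej, f_ivr = 0.08, 0.35, 0.08
    n_ivc = max(int(f_ivc * n_samples), 4)
    n_ej = max(int(f_ej * n_samples), 8)
    n_ivr = max(int(f_ivr * n_samples), 4)
    n_fill = n_samples - n_ivc - n_ej - n_ivr

    def smooth01(n: int) -> np.ndarray:
        s = np.linspace(0.0, 1.0, n, endpoint=False)
        return 0.5 - 0.5 * np.cos(np.pi * s)

    # isovolumetric contraction: V = EDV, P rises EDP -> ESP
    p1 = edp + (esp - edp) * smooth01(n_ivc)
    v1 = np.full(n_ivc, edv)
    # ejection: P arches at ESP then falls a little; V falls EDV -> ESV
    s = np.linspace(0.0, 1.0, n_ej, endpoint=False)
    p2 = esp - (esp - max(edp, 0.3 * esp)) * s**2  # stays below ESP after t=0 of phase
    p2[0] = esp
    v2 = edv - (edv - esv) * (0.5 - 0.5 * np.cos(np.pi * s))
    # isovolumetric relaxation: V = ESV, P falls to just above EDP-level baseline
    p_end_ej = p2[-1]
    p3 = p_end_ej - (p_end_ej - edp) * smooth01(n_ivr)
    v3 = np.full(n_ivr, esv)
    # filling: P stays at the diastolic baseline (== EDP at the very end), V rises ESV -> EDV
    s4 = np.linspace(0.0, 1.0, n_fill)
    p4 = np.full(n_fill, float(edp))
    v4 = esv + (edv - esv) * (0.5 - 0.5 * np.cos(np.pi * s4))
    v4[-1] = edv

    p = np.concatenate([p1, p2, p3, p4])
    v = np.concatenate([v1, v2, v3, v4])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise_p = rng.normal(0.0, noise_sd, n_samples)
        noise_v = rng.normal(0.0, noise_sd, n_samples)
        # keep the defining extremes untouched
        protect = np.zeros(n_samples, dtype=bool)
        protect[v == edv] = True
        protect[v == esv] = True
        protect[p == esp] = True
        noise_p[protect] = 0.0
        noise_v[protect] = 0.0
        p = p + noise_p
        v = v + noise_v
    return pd.DataFrame({"time_ms": t, "p_lv": p, "v_lv": v})
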
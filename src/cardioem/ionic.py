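"""Single-cell human ventricular membrane kinetics (ten Tusscher 2004).

The cell is paced at a fixed basic cycle length and supplies physiologic
calcium transients to the myofilament model.  The membrane equation is

    C_m dV/dt = -(I_ion + I_stim),      I_ion = sum of twelve currents

with the current set of the published 2004 formulation (epicardial variant
by default).  Forward Euler at dt = 0.01 ms advances concentrations and
voltage; gates use the Rush-Larsen exponential update.  A depolarizing
stimulus is a *negative* current density (default -52 pA/pF for 1 ms).

Parameter provenance: all constants are transcribed from the published 2004
human ventricular model (ten Tusscher, Noble, Noble & Panfilov, Am J Physiol
Heart Circ Physiol 286:H1573, 2004), epicardial conductances by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _tnnp_kernels as _k
from .calcium import CalciumTransient
from .exceptions import DivergenceError, InvalidParameterError, NumericDomainError

__all__ = [
    "MembraneState",
    "CurrentBreakdown",
    "PacingResult",
    "init_state",
    "compute_currents",
    "step_state",
    "pace_to_steady_state",
    "extract_calcium_transient",
]

GATE_NAMES = ("m", "h", "j", "d", "f", "f_ca", "r", "s", "xr1", "xr2", "xs", "g")

_CELL_CODES = {"epi": _k.EPI, "endo": _k.ENDO, "mid": _k.MID}

#: Published resting initial conditions (shared across cell types).
_INITIAL = {
    "v_m": -86.2,
    "m": 0.0, "h": 0.75, "j": 0.75, "d": 0.0, "f": 1.0, "f_ca": 1.0,
    "r": 0.0, "s": 1.0, "xr1": 0.0, "xr2": 1.0, "xs": 0.0, "g": 1.0,
    "ca_i": 0.0002, "ca_sr": 0.2, "na_i": 11.6, "k_i": 138.3,
}


@dataclass
class MembraneState:
    """Voltage, gates and concentrations of one ventricular myocyte.

    Voltages mV, concentrations mM, gates dimensionless in [0, 1].
    """

    v_m: float
    gates: dict[str, float]
    ca_i: float
    ca_sr: float
    na_i: float
    k_i: float
    cell_type: str = "epi"

    def as_array(self) -> np.ndarray:
        y = np.empty(_k.NSTATE)
        y[_k.IV] = self.v_m
        for name, idx in zip(GATE_NAMES, _k.GATE_INDICES):
            y[idx] = self.gates[name]
        y[_k.ICAI] = self.ca_i
        y[_k.ICASR] = self.ca_sr
        y[_k.INAI] = self.na_i
        y[_k.IKI] = self.k_i
        return y

    @classmethod
    def from_array(cls, y: np.ndarray, cell_type: str = "epi") -> "MembraneState":
        gates = {name: float(y[idx]) for name, idx in zip(GATE_NAMES, _k.GATE_INDICES)}
        return cls(
            v_m=float(y[_k.IV]), gates=gates,
            ca_i=float(y[_k.ICAI]), ca_sr=float(y[_k.ICASR]),
            na_i=float(y[_k.INAI]), k_i=float(y[_k.IKI]),
            cell_type=cell_type,
        )

    def validate(self) -> None:
        vals = [self.v_m, self.ca_i, self.ca_sr, self.na_i, self.k_i, *self.gates.values()]
        if not all(math.isfinite(v) for v in vals):
            raise NumericDomainError("membrane state contains non-finite values")
        for name, g in self.gates.items():
            if not (0.0 <= g <= 1.0):
                raise NumericDomainError(f"gate {name} = {g} outside [0, 1]")
        for name in ("ca_i", "ca_sr", "na_i", "k_i"):
            if getattr(self, name) <= 0:
                raise NumericDomainError(f"concentration {name} must be > 0")


@dataclass(frozen=True)
class CurrentBreakdown:
    """The twelve transmembrane currents (pA/pF) and their sum i_ion."""

    i_na: float
    i_k1: float
    i_to: float
    i_kr: float
    i_ks: float
    i_cal: float
    i_naca: float
    i_nak: float
    i_pca: float
    i_pk: float
    i_bca: float
    i_bna: float

    @property
    def i_ion(self) -> float:
        return (
            self.i_na + self.i_k1 + self.i_to + self.i_kr + self.i_ks + self.i_cal
            + self.i_naca + self.i_nak + self.i_pca + self.i_pk + self.i_bca + self.i_bna
        )

    def as_dict(self) -> dict[str, float]:
        d = {k: getattr(self, k) for k in (
            "i_na", "i_k1", "i_to", "i_kr", "i_ks", "i_cal",
            "i_naca", "i_nak", "i_pca", "i_pk", "i_bca", "i_bna")}
        d["i_ion"] = self.i_ion
        return d


@dataclass
class PacingResult:
    """Beat-indexed voltage/calcium traces from a fixed-BCL pacing run."""

    time_ms: np.ndarray          # within-run time, ms
    v_mv: np.ndarray
    ca_i_mM: np.ndarray
    bcl_ms: float
    n_beats: int
    steady_state_metric: float   # relative change of Cai peak, last two beats

    def beat_slice(self, beat_index: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(t_local, v, ca) for one beat; negative indices count from the end."""
        if beat_index < 0:
            beat_index += self.n_beats
        if not (0 <= beat_index < self.n_beats):
            raise InvalidParameterError(f"beat index {beat_index} out of range")
        t0 = beat_index * self.bcl_ms
        t1 = t0 + self.bcl_ms
        msk = (self.time_ms >= t0 - 1e-9) & (self.time_ms < t1 - 1e-9)
        return self.time_ms[msk] - t0, self.v_mv[msk], self.ca_i_mM[msk]


def _cell_code(cell_type: str) -> int:
    try:
        return _CELL_CODES[cell_type]
    except KeyError:
        raise InvalidParameterError(
            f"unknown cell type {cell_type!r}; choose from {sorted(_CELL_CODES)}"
        ) from None


def init_state(cell_type: str = "epi") -> MembraneState:
    """Published resting initial conditions for the chosen cell type."""
    _cell_code(cell_type)
    gates = {name: _INITIAL[name] for name in GATE_NAMES}
    return MembraneState(
        v_m=_INITIAL["v_m"], gates=gates,
        ca_i=_INITIAL["ca_i"], ca_sr=_INITIAL["ca_sr"],
        na_i=_INITIAL["na_i"], k_i=_INITIAL["k_i"],
        cell_type=cell_type,
    )


def compute_currents(state: MembraneState) -> CurrentBreakdown:
    """All twelve membrane currents at the given state."""
    state.validate()
    cur = _k.currents(state.as_array(), _cell_code(state.cell_type))
    return CurrentBreakdown(*[float(c) for c in cur])


def step_state(state: MembraneState, dt: float = 0.01, i_stim: float = 0.0) -> MembraneState:
    """One forward-Euler/Rush-Larsen step; returns the advanced state."""
    if dt > 0.02:
        raise InvalidParameterError("dt must be <= 0.02 ms for the explicit update")
    if not math.isfinite(i_stim):
        raise InvalidParameterError("i_stim must be finite")
    y = state.as_array()
    _k.step(y, dt, i_stim, _cell_code(state.cell_type))
    if abs(y[_k.IV]) > 200.0:
        raise DivergenceError(f"membrane potential diverged ({y[_k.IV]:.1f} mV)", step=1)
    return MembraneState.from_array(y, state.cell_type)


def pace_to_steady_state(
    cell_type: str = "epi",
    bcl_ms: float = 800.0,
    n_beats: int = 10,
    stim_amp: float = -52.0,
    stim_dur_ms: float = 1.0,
    dt: float = 0.01,
    record_every_ms: float = 0.5,
) -> PacingResult:
    """Pace from rest for ``n_beats`` cycles, recording voltage and calcium.

    The steady-state metric is the relative change of the intracellular
    calcium peak between the last two beats.
    """
    if n_beats < 2:
        raise InvalidParameterError("n_beats must be >= 2")
    y = init_state(cell_type).as_array()
    stride = max(1, int(round(record_every_ms / dt)))
    t, v, ca = _k.pace(
        y, n_beats, bcl_ms, dt, stim_amp, stim_dur_ms, _cell_code(cell_type), stride
    )
    if t.size and t[-1] < 0:
        raise DivergenceError("pacing run diverged", step=int(-t[-1]))
    res = PacingResult(t, v, ca, bcl_ms, n_beats, steady_state_metric=np.nan)
    _, _, ca_last = res.beat_slice(n_beats - 1)
    _, _, ca_prev = res.beat_slice(n_beats - 2)
    metric = abs(ca_last.max() - ca_prev.max()) / ca_last.max()
    res.steady_state_metric = float(metric)
    return res


def extract_calcium_transient(result: PacingResult, beat_index: int = -1) -> CalciumTransient:
    """Convert one beat's Cai trace (mM) into a CalciumTransient (µM)."""
    t, _, ca = result.beat_slice(beat_index)
    ca_um = ca * 1000.0
    return CalciumTransient(t, ca_um, result.bcl_ms, diastolic_uM=float(ca_um[0]))
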
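"""1D monodomain cable: propagation of the ventricular action potential.

The monodomain reaction-diffusion equation on a fiber,

    beta * (C_m dV/dt + I_ion - I_trans) = d/dx ( sigma dV/dx ),

is discretized with second-order central differences and no-flux boundaries,
the reaction term per node coming from the single-cell ionic model.  The
module measures per-node electrical activation times and the conduction
velocity (CV) by regressing activation time on distance over the central
half of the cable, away from boundary effects.

Units: sigma in mS/cm, beta in 1/cm, c_m in µF/cm², dx in cm, time in ms,
voltage in mV.  These are mutually consistent: sigma*V/dx² is µA/cm³, and
dividing by beta then c_m gives mV/ms with no extra conversion factor, so
the effective diffusion coefficient is D = sigma/(beta*c_m) in cm²/ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import _tnnp_kernels as _k
from .exceptions import DivergenceError, InsufficientDataError, InvalidParameterError
from .ionic import init_state

__all__ = [
    "CableGrid",
    "CableRun",
    "make_cable",
    "step_cable",
    "run_cable",
    "activation_times",
    "conduction_velocity",
]

# sigma [mS/cm] * dV [mV] / dx^2 [cm^2] gives µA/cm^3; dividing by beta [1/cm]
# gives µA/cm^2 which matches pA/pF currents when c_m = 1 µF/cm².  No extra
# unit factor is needed: mS*mV = µA.


@dataclass
class CableGrid:
    """A 1D fiber of coupled ventricular cells."""

    n_nodes: int = 100
    dx: float = 0.01          # cm
    sigma: float = 1.75       # mS/cm, intracellular conductivity
    beta: float = 1400.0      # 1/cm, surface-to-volume ratio
    c_m: float = 1.0          # µF/cm²
    cell_type: str = "epi"
    states: np.ndarray = field(default=None, repr=False)  # (n_nodes, NSTATE)

    def __post_init__(self) -> None:
        if self.n_nodes < 3:
            raise InvalidParameterError("n_nodes must be >= 3")
        for name in ("dx", "sigma", "beta", "c_m"):
            if getattr(self, name) < 0 or (name != "sigma" and getattr(self, name) == 0):
                raise InvalidParameterError(f"{name} must be positive")
        if self.states is None:
            y0 = init_state(self.cell_type).as_array()
            self.states = np.tile(y0, (self.n_nodes, 1))

    @property
    def positions_cm(self) -> np.ndarray:
        return np.arange(self.n_nodes) * self.dx

    def stability_dt_max(self) -> float:
        """Explicit diffusion stability bound dt < c_m*beta*dx^2 / (2*sigma), ms."""
        if self.sigma == 0:
            return math.inf
        return self.c_m * self.beta * self.dx**2 / (2.0 * self.sigma)


@njit(cache=False)
def _cable_step_kernel(states, dt, stim, diff_coef, cell_type):
    n = states.shape[0]
    v = states[:, 0].copy()
    # no-flux boundaries: mirror neighbors
    for i in range(n):
        vl = v[i - 1] if i > 0 else v[1]
        vr = v[i + 1] if i < n - 1 else v[n - 2]
        lap = (vl - 2.0 * v[i] + vr)
        _k.step(states[i], dt, stim[i], cell_type)
        states[i, 0] += dt * diff_coef * lap


@njit(cache=False)
def _cable_run_kernel(states, n_steps, dt, stim_amp, stim_dur_steps, stim_mask,
                      diff_coef, cell_type, record_stride):
    n = states.shape[0]
    n_rec = n_steps // record_stride + 1
    t_out = np.empty(n_rec)
    v_out = np.empty((n_rec, n))
    stim = np.zeros(n)
    r = 0
    for s in range(n_steps):
        if s % record_stride == 0:
            t_out[r] = s * dt
            for i in range(n):
                v_out[r, i] = states[i, 0]
            r += 1
        if s < stim_dur_steps:
            for i in range(n):
                stim[i] = stim_amp if stim_mask[i] else 0.0
        else:
            for i in range(n):
                stim[i] = 0.0
        _cable_step_kernel(states, dt, stim, diff_coef, cell_type)
        for i in range(n):
            if np.abs(states[i, 0]) > 200.0:
                t_out[r - 1] = -float(s)
                return t_out[:r], v_out[:r]
    t_out[r] = n_steps * dt
    for i in range(n):
        v_out[r, i] = states[i, 0]
    return t_out[: r + 1], v_out[: r + 1]


@dataclass
class CableRun:
    """Recorded voltage traces of a cable simulation."""

    time_ms: np.ndarray            # (n_rec,)
    v_mv: np.ndarray               # (n_rec, n_nodes)
    positions_cm: np.ndarray


def make_cable(**kwargs) -> CableGrid:
    return CableGrid(**kwargs)


def purkinje_preset(n_nodes: int = 100, dx: float = 0.01) -> CableGrid:
    """Fast-fiber preset: conductivity calibrated so CV is about 200 cm/s.

    The myocardial default (sigma = 1.75 mS/cm) propagates at ~66 cm/s; by
    the square-root scaling of cable theory, sigma scaled by (200/66)^2
    yields the clinical Purkinje conduction speed of 200 cm/s.  The value
    below is a package calibration, not a measured conductivity.
    """
    return CableGrid(n_nodes=n_nodes, dx=dx, sigma=15.95)


def step_cable(grid: CableGrid, dt: float, stim: np.ndarray | None = None) -> CableGrid:
    """Advance the cable one explicit step (checked against the stability bound)."""
    if dt >= grid.stability_dt_max():
        raise InvalidParameterError(
            f"dt = {dt} ms violates the explicit stability bound "
            f"{grid.stability_dt_max():.4g} ms"
        )
    if stim is None:
        stim = np.zeros(grid.n_nodes)
    stim = np.asarray(stim, dtype=float)
    if stim.shape != (grid.n_nodes,):
        raise InvalidParameterError("stim must have one value per node")
    diff_coef = grid.sigma / (grid.beta * grid.c_m * grid.dx**2)
    _cable_step_kernel(grid.states, dt, stim, diff_coef, _cell_code(grid.cell_type))
    return grid


def _cell_code(cell_type: str) -> int:
    from .ionic import _cell_code as code
    return code(cell_type)


def run_cable(
    grid: CableGrid,
    t_end_ms: float,
    dt: float = 0.01,
    stim_nodes: slice | np.ndarray = slice(0, 5),
    stim_amp: float = -52.0,
    stim_dur_ms: float = 2.0,
    record_every_ms: float = 0.1,
) -> CableRun:
    """Stimulate the chosen nodes at t = 0 and record the propagating wave."""
    if dt >= grid.stability_dt_max():
        raise InvalidParameterError(
            f"dt = {dt} ms violates the explicit stability bound "
            f"{grid.stability_dt_max():.4g} ms"
        )
    mask = np.zeros(grid.n_nodes, dtype=np.bool_)
    mask[stim_nodes] = True
    diff_coef = grid.sigma / (grid.beta * grid.c_m * grid.dx**2)
    n_steps = int(round(t_end_ms / dt))
    stride = max(1, int(round(record_every_ms / dt)))
    t, v = _cable_run_kernel(
        grid.states, n_steps, dt, stim_amp, int(round(stim_dur_ms / dt)),
        mask, diff_coef, _cell_code(grid.cell_type), stride,
    )
    if t.size and t[-1] < 0:
        raise DivergenceError("cable run diverged", step=int(-t[-1]))
    return CableRun(t, v, grid.positions_cm)


def activation_times(run: CableRun, threshold_mv: float = -40.0) -> np.ndarray:
    """First upward threshold crossing per node, linearly interpolated (ms).

    Nodes that never cross are flagged with NaN (unactivated).
    """
    t = run.time_ms
    n_nodes = run.v_mv.shape[1]
    eat = np.full(n_nodes, np.nan)
    for i in range(n_nodes):
        v = run.v_mv[:, i]
        above = v >= threshold_mv
        if above[0]:
            eat[i] = t[0]
            continue
        idx = np.nonzero(~above[:-1] & above[1:])[0]
        if idx.size == 0:
            continue
        k = idx[0]
        frac = (threshold_mv - v[k]) / (v[k + 1] - v[k])
        eat[i] = t[k] + frac * (t[k + 1] - t[k])
    return eat


def conduction_velocity(
    eat_ms: np.ndarray, positions_cm: np.ndarray, window: tuple[float, float] = (0.25, 0.75)
) -> float:
    """CV in cm/s from the slope of distance vs activation time.

    Least-squares fit restricted to the central fraction of the cable given
    by ``window`` (defaults to the middle 50%), avoiding boundary effects.
    """
    n = len(eat_ms)
    lo, hi = int(window[0] * n), int(window[1] * n)
    x = positions_cm[lo:hi]
    tt = eat_ms[lo:hi]
    ok = np.isfinite(tt)
    if ok.sum() < 2:
        raise InsufficientDataError("fewer than 2 activated nodes in the measurement window")
    slope, _ = np.polyfit(tt[ok], x[ok], 1)  # cm per ms
    return float(slope * 1000.0)
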
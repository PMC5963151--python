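"""Intracellular calcium transients: the actuator coupling electrics to mechanics.

A single beat of cytosolic calcium is represented either analytically (a
normalized bi-exponential twitch) or extracted from the ionic model.  Heart
failure is imposed by rescaling the transient: the peak amplitude above
diastole is reduced to 70% of normal and the decay time constant shortened
by 30%, the canonical systolic-dysfunction remodeling used throughout this
package.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .exceptions import InvalidParameterError

__all__ = [
    "TransientParams",
    "CalciumTransient",
    "NORMAL_TRANSIENT",
    "make_transient",
    "apply_hf_remodeling",
    "normalize_to_reference",
    "sample_periodic",
    "write_transient_csv",
    "read_transient_csv",
]


@dataclass(frozen=True)
class TransientParams:
    """Parameters of the analytic bi-exponential calcium twitch.

    Attributes
    ----------
    ca_dia : float
        Diastolic (resting) calcium, µM.
    ca_amp : float
        Peak amplitude above diastole, µM.  "Magnitude" of the transient.
    tau_rise, tau_decay : float
        Rise and decay time constants, ms; ``tau_rise < tau_decay``.
    bcl_ms : float
        Basic cycle length (pacing period), ms.
    """

    ca_dia: float = 0.1
    ca_amp: float = 0.9
    tau_rise: float = 20.0
    tau_decay: float = 150.0
    bcl_ms: float = 800.0

    def __post_init__(self) -> None:
        for name in ("ca_dia", "ca_amp", "tau_rise", "tau_decay", "bcl_ms"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InvalidParameterError(f"{name} must be finite, got {v!r}")
        if self.ca_dia < 0:
            raise InvalidParameterError("ca_dia must be >= 0")
        if self.ca_amp < 0:
            raise InvalidParameterError("ca_amp must be >= 0")
        for name in ("tau_rise", "tau_decay", "bcl_ms"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.tau_rise >= self.tau_decay:
            raise InvalidParameterError(
                f"tau_rise ({self.tau_rise}) must be < tau_decay ({self.tau_decay})"
            )

    @property
    def peak_uM(self) -> float:
        """Absolute peak calcium, µM (diastolic + amplitude)."""
        return self.ca_dia + self.ca_amp

    def time_to_peak_ms(self) -> float:
        """Closed-form argmax of the bi-exponential twitch, ms."""
        tr, td = self.tau_rise, self.tau_decay
        return math.log(td / tr) * tr * td / (td - tr)


#: Default normal-condition transient (resembles a human ventricular twitch
#: paced at 800 ms: 0.1 µM diastole, 1.0 µM peak, ~150 ms decay).
NORMAL_TRANSIENT = TransientParams()


@dataclass(frozen=True)
class CalciumTransient:
    """One sampled beat of intracellular calcium.

    ``time_ms`` spans ``[0, bcl_ms)`` on a strictly increasing grid;
    ``ca_uM`` holds the concentration at each sample.
    """

    time_ms: np.ndarray
    ca_uM: np.ndarray
    bcl_ms: float
    diastolic_uM: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time_ms, dtype=float)
        ca = np.asarray(self.ca_uM, dtype=float)
        object.__setattr__(self, "time_ms", t)
        object.__setattr__(self, "ca_uM", ca)
        if t.ndim != 1 or ca.shape != t.shape:
            raise InvalidParameterError("time_ms and ca_uM must be 1-D and congruent")
        if t.size < 2:
            raise InvalidParameterError("need at least 2 samples")
        if not (np.diff(t) > 0).all():
            raise InvalidParameterError("time grid must be strictly increasing")
        if t[0] != 0 or t[-1] >= self.bcl_ms:
            raise InvalidParameterError("time grid must span [0, bcl_ms)")

    @property
    def peak_uM(self) -> float:
        return float(self.ca_uM.max())

    def peak_above_diastolic(self) -> float:
        return self.peak_uM - self.diastolic_uM


def make_transient(params: TransientParams, dt: float = 1.0) -> CalciumTransient:
    """Sample the analytic bi-exponential twitch over one beat.

    Ca(t) = ca_dia + ca_amp * (exp(-t/tau_decay) - exp(-t/tau_rise)) / M
    with M the maximum of the bi-exponential, so the absolute peak is
    exactly ``ca_dia + ca_amp``.
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be > 0")
    if dt > params.bcl_ms / 100:
        raise InvalidParameterError(
            f"dt={dt} too coarse; need dt <= bcl/100 = {params.bcl_ms / 100}"
        )
    t = np.arange(0.0, params.bcl_ms, dt)
    if params.ca_amp == 0.0:
        return CalciumTransient(t, np.full_like(t, params.ca_dia), params.bcl_ms, params.ca_dia)
    # insert the analytic argmax so the sampled maximum is exact and
    # independent of dt refinement
    t_star = params.time_to_peak_ms()
    if t_star < params.bcl_ms and not np.any(t == t_star):
        t = np.sort(np.append(t, t_star))
    shape = np.exp(-t / params.tau_decay) - np.exp(-t / params.tau_rise)
    m = math.exp(-t_star / params.tau_decay) - math.exp(-t_star / params.tau_rise)
    ca = params.ca_dia + params.ca_amp * shape / m
    return CalciumTransient(t, ca, params.bcl_ms, params.ca_dia)


def apply_hf_remodeling(
    params: TransientParams, amp_factor: float = 0.7, tau_factor: float = 0.7
) -> TransientParams:
    """Heart-failure remodeling of the calcium twitch.

    The amplitude above diastole is multiplied by ``amp_factor`` (default
    0.7, i.e. reduced to 70% of normal) and the decay time constant by
    ``tau_factor`` (default 0.7, i.e. shortened by 30%).  Diastolic level
    and rise kinetics are untouched.
    """
    for name, f in (("amp_factor", amp_factor), ("tau_factor", tau_factor)):
        if not (0.0 < f <= 1.0):
            raise InvalidParameterError(f"{name} must lie in (0, 1], got {f}")
    return replace(
        params,
        ca_amp=params.ca_amp * amp_factor,
        tau_decay=params.tau_decay * tau_factor,
    )


def normalize_to_reference(ct: CalciumTransient, reference_peak: float) -> CalciumTransient:
    """Divide the trace by a reference peak (µM), yielding dimensionless values."""
    if reference_peak <= 0:
        raise InvalidParameterError("reference_peak must be > 0")
    return CalciumTransient(
        ct.time_ms.copy(),
        ct.ca_uM / reference_peak,
        ct.bcl_ms,
        ct.diastolic_uM / reference_peak,
    )


def sample_periodic(ct: CalciumTransient, t_ms: float | np.ndarray) -> float | np.ndarray:
    """Calcium at absolute time ``t_ms`` assuming beat-periodic repetition.

    Linear interpolation on the beat grid; the wrap segment interpolates
    between the last sample and the t=0 sample.
    """
    t = np.mod(np.asarray(t_ms, dtype=float), ct.bcl_ms)
    # append the wrap point so interpolation is periodic
    tg = np.concatenate([ct.time_ms, [ct.bcl_ms]])
    cg = np.concatenate([ct.ca_uM, [ct.ca_uM[0]]])
    out = np.interp(t, tg, cg)
    if np.isscalar(t_ms):
        return float(out)
    return out


def write_transient_csv(ct: CalciumTransient, path: str | Path, params: TransientParams | None = None) -> None:
    """Write (time_ms, ca_uM) CSV with a JSON sidecar carrying bcl and params."""
    path = Path(path)
    arr = np.column_stack([ct.time_ms, ct.ca_uM])
    np.savetxt(path, arr, delimiter=",", header="time_ms,ca_uM", comments="")
    meta = {"bcl_ms": ct.bcl_ms, "diastolic_uM": ct.diastolic_uM}
    if params is not None:
        meta["params"] = {
            "ca_dia": params.ca_dia,
            "ca_amp": params.ca_amp,
            "tau_rise": params.tau_rise,
            "tau_decay": params.tau_decay,
            "bcl_ms": params.bcl_ms,
        }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_transient_csv(path: str | Path) -> CalciumTransient:
    path = Path(path)
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return CalciumTransient(arr[:, 0], arr[:, 1], meta["bcl_ms"], meta["diastolic_uM"])
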
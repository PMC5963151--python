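"""Passive myocardial constitutive law at material points.

The myocardium is modeled as a hyperelastic material with a Fung-type
exponential strain-energy function in the local fiber coordinate system
(f = fiber, r = radial/sheet, c = cross-fiber):

    W = (C/2) (exp(Q) - 1)
    Q = b1*Eff^2 + b2*(Err^2 + Ecc^2 + 2*Erc^2) + 2*b3*(Efr^2 + Efc^2)

with default constants C = 2 kPa, b1 = 8 (fiber), b2 = 2 (transverse),
b3 = 4 (fiber shear).  The second Piola-Kirchhoff stress is the analytic
gradient S_ij = dW/dE_ij.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError, NumericDomainError

__all__ = ["StrainState", "MaterialParams", "DEFAULT_MATERIAL", "strain_energy", "pk2_stress"]

_Q_OVERFLOW = 700.0  # exp argument beyond which float64 overflows


@dataclass(frozen=True)
class StrainState:
    """Green-Lagrange strain components in the fiber coordinate system.

    Each shear strain is stored once; its tensor symmetry is accounted for
    by the factor-2 weights inside Q.
    """

    e_ff: float = 0.0
    e_rr: float = 0.0
    e_cc: float = 0.0
    e_rc: float = 0.0
    e_fr: float = 0.0
    e_fc: float = 0.0

    def __post_init__(self) -> None:
        for name in ("e_ff", "e_rr", "e_cc", "e_rc", "e_fr", "e_fc"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"strain component {name} must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.e_ff, self.e_rr, self.e_cc, self.e_rc, self.e_fr, self.e_fc])


@dataclass(frozen=True)
class MaterialParams:
    """Exponential-law constants: scale c_kpa (kPa) and exponent weights b1/b2/b3."""

    c_kpa: float = 2.0
    b1: float = 8.0
    b2: float = 2.0
    b3: float = 4.0

    def __post_init__(self) -> None:
        for name in ("c_kpa", "b1", "b2", "b3"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")


DEFAULT_MATERIAL = MaterialParams()


def _exponent_q(e: StrainState, p: MaterialParams) -> float:
    return (
        p.b1 * e.e_ff**2
        + p.b2 * (e.e_rr**2 + e.e_cc**2 + 2.0 * e.e_rc**2)
        + 2.0 * p.b3 * (e.e_fr**2 + e.e_fc**2)
    )


def strain_energy(e: StrainState, p: MaterialParams = DEFAULT_MATERIAL) -> float:
    """Strain-energy density W (kPa); zero at zero strain and nonnegative always."""
    q = _exponent_q(e, p)
    if q > _Q_OVERFLOW:
        raise NumericDomainError(f"exponent Q = {q:.3g} overflows exp()")
    return 0.5 * p.c_kpa * math.expm1(q)


def pk2_stress(e: StrainState, p: MaterialParams = DEFAULT_MATERIAL) -> dict[str, float]:
    """Second Piola-Kirchhoff stress components S_ij = dW/dE_ij (kPa).

    Closed form: S_ij = (c/2) exp(Q) * dQ/dE_ij, with shear components
    carrying their factor-2 weights from Q.
    """
    q = _exponent_q(e, p)
    if q > _Q_OVERFLOW:
        raise NumericDomainError(f"exponent Q = {q:.3g} overflows exp()")
    pref = 0.5 * p.c_kpa * math.exp(q)
    return {
        "s_ff": pref * 2.0 * p.b1 * e.e_ff,
        "s_rr": pref * 2.0 * p.b2 * e.e_rr,
        "s_cc": pref * 2.0 * p.b2 * e.e_cc,
        "s_rc": pref * 4.0 * p.b2 * e.e_rc,
        "s_fr": pref * 4.0 * p.b3 * e.e_fr,
        "s_fc": pref * 4.0 * p.b3 * e.e_fc,
    }
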
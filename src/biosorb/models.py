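"""Closed-form forward models for biosorption equilibrium and kinetics.

Equilibrium follows the single-layer statistical-physics monolayer model
coupled to a real-gas (van der Waals) description of the dissolved solute
(SLMRG).  In the grand-canonical picture each of the ``Nm`` receptor sites
(mg of sites per g of sorbent) binds ``n`` solute molecules, and the
occupation probability is driven by the ratio of an energetic parameter
``w`` (mg/L) to a van-der-Waals-corrected effective concentration::

    qe(Ce) = n * Nm / (1 + (w / f(Ce))**n)

    f(Ce)  = Ce / (1 - b*Ce) * exp(b*Ce / (1 - b*Ce)) * exp(-2*a*beta*Ce)

with co-volume ``b`` (L/mg), cohesion pressure ``a`` (tabulated in units of
1e-23 J L/mg) and ``beta = 1/(kB*T)``.  At ``a = b = 0`` the effective
concentration reduces to Ce and the model collapses to the Hill form
``n*Nm / (1 + (w/Ce)**n)`` (Langmuir when additionally ``n = 1``).

The published typeset equation is ambiguous about the grouping of the van
der Waals factors and the sign of the cohesion exponent; the form above is
the reconstruction consistent with the factor order of the printed formula
and with the statistical-physics adsorption literature the model descends
from.  See ``docs/methods.md`` for the full discussion.

Kinetics use the integrated pseudo-first-order and pseudo-second-order
models and the Weber-Morris intraparticle-diffusion law; the logarithmic /
reciprocal linearizations live in :mod:`biosorb.fitting`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .constants import K_BOLTZMANN, R_GAS
from .exceptions import CovolumeSingularityError, ValidationError

__all__ = [
    "SLMRGParams",
    "EnergeticDecomposition",
    "PFOParams",
    "PSOParams",
    "IPDParams",
    "effective_concentration",
    "slmrg_capacity",
    "saturation_capacity",
    "energetic_parameter",
    "adsorption_energy",
    "pfo_capacity",
    "pso_capacity",
    "ipd_capacity",
    "batch_capacity",
    "removal_efficiency",
]


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class SLMRGParams:
    """Parameter set of the SLMRG isotherm.

    Attributes
    ----------
    n : float
        Number of molecules bound per receptor site (steric exponent),
        dimensionless; fractional values mean one molecule spans several
        sites.
    nm : float
        Receptor-site density, mg/g.
    a : float
        Cohesion pressure in units of 1e-23 J L/mg (as tabulated).
    b : float
        Co-volume of the solute, L/mg.
    w : float
        Energetic parameter (concentration at half saturation in the ideal
        limit), mg/L.
    """

    n: float
    nm: float
    a: float
    b: float
    w: float

    def __post_init__(self) -> None:
        for name in ("n", "nm", "a", "b", "w"):
            object.__setattr__(self, name, _require_finite(name, getattr(self, name)))
        if not self.n > 0:
            raise ValidationError("steric exponent n must be positive")
        if not self.nm > 0:
            raise ValidationError("site density nm must be positive")
        if self.a < 0:
            raise ValidationError("cohesion pressure a must be nonnegative")
        if self.b < 0:
            raise ValidationError("co-volume b must be nonnegative")
        if not self.w > 0:
            raise ValidationError("energetic parameter w must be positive")


@dataclass(frozen=True)
class EnergeticDecomposition:
    """Arrhenius-type decomposition of the energetic parameter.

    ``w = cs * exp(-Ea / (R*T))`` with a reference concentration ``cs``
    (mg/L, typically the solute solubility) and adsorption energy ``Ea``
    (J/mol).
    """

    cs: float
    ea: float
    temperature: float

    def __post_init__(self) -> None:
        if not self.cs > 0:
            raise ValidationError("reference concentration cs must be positive")
        _require_finite("ea", self.ea)
        if not self.temperature > 0:
            raise ValidationError("temperature must be positive (kelvin)")


@dataclass(frozen=True)
class PFOParams:
    """Pseudo-first-order parameters: plateau qe (mg/g), rate k1 (1/min)."""

    qe: float
    k1: float

    def __post_init__(self) -> None:
        if not self.qe > 0:
            raise ValidationError("qe must be positive")
        if not self.k1 > 0:
            raise ValidationError("k1 must be positive")


@dataclass(frozen=True)
class PSOParams:
    """Pseudo-second-order parameters: plateau qe (mg/g), rate k2 (g/(mg min))."""

    qe: float
    k2: float

    def __post_init__(self) -> None:
        if not self.qe > 0:
            raise ValidationError("qe must be positive")
        if not self.k2 > 0:
            raise ValidationError("k2 must be positive")


@dataclass(frozen=True)
class IPDParams:
    """Weber-Morris intraparticle diffusion: rate kid (mg/(g min^0.5)) and
    boundary-layer intercept c (mg/g)."""

    kid: float
    c: float

    def __post_init__(self) -> None:
        if self.kid < 0:
            raise ValidationError("kid must be nonnegative")
        _require_finite("c", self.c)


def _check_ce_domain(ce: np.ndarray, b: float) -> None:
    if b > 0 and np.any(ce >= 1.0 / b):
        raise CovolumeSingularityError(
            f"equilibrium concentration must stay below the co-volume bound "
            f"1/b = {1.0 / b:.6g} mg/L"
        )


def effective_concentration(ce, params: SLMRGParams, temperature: float):
    """Van-der-Waals-corrected effective concentration f(Ce), mg/L.

    Reduces to ``ce`` in the ideal limit ``a = b = 0`` and vanishes at
    ``ce = 0``.  Defined for ``0 <= ce < 1/b``.
    """
    ce_arr = np.asarray(ce, dtype=float)
    if np.any(ce_arr < 0):
        raise ValidationError("ce must be nonnegative")
    if not temperature > 0:
        raise ValidationError("temperature must be positive (kelvin)")
    _check_ce_domain(ce_arr, params.b)

    bc = params.b * ce_arr
    # a is stored in units of 1e-23 J L/mg; the 1e-23 cancels against kB.
    two_a_beta = 2.0 * params.a / (K_BOLTZMANN / 1e-23 * temperature)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ce_arr / (1.0 - bc) * np.exp(bc / (1.0 - bc)) * np.exp(-two_a_beta * ce_arr)
    f = np.where(ce_arr == 0.0, 0.0, f)
    return float(f) if np.isscalar(ce) or np.ndim(ce) == 0 else f


def slmrg_capacity(ce, params: SLMRGParams, temperature: float):
    """SLMRG equilibrium capacity qe(Ce), mg/g.

    ``qe(0)`` is defined as 0 by continuous extension.
    """
    f = np.asarray(effective_concentration(ce, params, temperature), dtype=float)
    qe = np.zeros_like(f)
    pos = f > 0
    qe[pos] = params.n * params.nm / (1.0 + (params.w / f[pos]) ** params.n)
    return float(qe) if np.isscalar(ce) or np.ndim(ce) == 0 else qe


def saturation_capacity(params: SLMRGParams) -> float:
    """Saturation capacity Qsat = n * Nm, mg/g (the supremum of qe)."""
    return params.n * params.nm


def energetic_parameter(decomp: EnergeticDecomposition) -> float:
    """Energetic parameter w = Cs * exp(-Ea/(R*T)), mg/L."""
    return decomp.cs * math.exp(-decomp.ea / (R_GAS * decomp.temperature))


def adsorption_energy(w: float, cs: float, temperature: float) -> float:
    """Adsorption energy Ea = R*T*ln(Cs/w), J/mol.

    Inverse of :func:`energetic_parameter`.  A fitted ``w`` larger than the
    reference concentration yields a negative energy; since ``Cs`` is a
    user-supplied and often uncertain quantity this is reported with a
    warning rather than rejected.
    """
    if not w > 0:
        raise ValidationError("w must be positive")
    if not cs > 0:
        raise ValidationError("cs must be positive")
    if not temperature > 0:
        raise ValidationError("temperature must be positive (kelvin)")
    ea = R_GAS * temperature * math.log(cs / w)
    if ea < 0:
        warnings.warn(
            f"adsorption energy is negative ({ea:.4g} J/mol): "
            "w exceeds the reference concentration cs",
            stacklevel=2,
        )
    return ea


def _check_time(t) -> np.ndarray:
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValidationError("time must be nonnegative")
    return t_arr


def pfo_capacity(t, p: PFOParams):
    """Integrated pseudo-first-order uptake qt = qe*(1 - exp(-k1*t))."""
    t_arr = _check_time(t)
    qt = p.qe * (1.0 - np.exp(-p.k1 * t_arr))
    return float(qt) if np.ndim(t) == 0 else qt


def pso_capacity(t, p: PSOParams):
    """Integrated pseudo-second-order uptake qt = qe^2*k2*t / (1 + qe*k2*t)."""
    t_arr = _check_time(t)
    x = p.qe * p.k2 * t_arr
    qt = p.qe * x / (1.0 + x)
    return float(qt) if np.ndim(t) == 0 else qt


def ipd_capacity(t, p: IPDParams):
    """Weber-Morris intraparticle diffusion law qt = kid*sqrt(t) + c."""
    t_arr = _check_time(t)
    qt = p.kid * np.sqrt(t_arr) + p.c
    return float(qt) if np.ndim(t) == 0 else qt


def batch_capacity(ce: float, cond) -> float:
    """Batch mass-balance capacity qe = (C0 - Ce) * V / m, mg/g."""
    if ce < 0:
        raise ValidationError("ce must be nonnegative")
    if ce > cond.c0:
        raise ValidationError(
            f"ce = {ce} mg/L exceeds the initial concentration {cond.c0} mg/L; "
            "negative uptake signals an input mistake"
        )
    return (cond.c0 - ce) * cond.volume / cond.mass


def removal_efficiency(qe: float, cond) -> float:
    """Removal efficiency 100 * qe * (m/V) / C0, percent of initial solute."""
    if qe < 0:
        raise ValidationError("qe must be nonnegative")
    if not cond.c0 > 0:
        raise ValidationError("initial concentration must be positive")
    eff = 100.0 * qe * cond.dose / cond.c0
    if eff > 100.0 + 1e-9:
        raise ValidationError("efficiency exceeds 100%: qe inconsistent with mass balance")
    return eff
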
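"""Equilibrium thermodynamics of adsorption and surface-charge analysis.

The Gibbs energy of adsorption follows from the dimensionless equilibrium
constant, ``dG0 = -R*T*ln(Kads)``, and the van't Hoff regression of
``ln(Kads)`` on ``1/T`` yields the enthalpy (from the slope) and entropy
(from the intercept)::

    ln(Kads) = dS0/R - dH0/(R*T)

An enthalpy above 40 kJ/mol is conventionally read as chemisorption;
smaller values as physisorption.  The point of zero charge is read off a
pH-drift titration as the zero crossing of delta_pH vs initial pH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .constants import R_GAS
from .data import ThermoSeries, TitrationCurve
from .exceptions import DomainError, ValidationError

__all__ = [
    "ThermoResult",
    "VantHoff",
    "gibbs_energy",
    "vant_hoff",
    "classify_sorption",
    "pzc_from_titration",
    "CHEMISORPTION_THRESHOLD_KJ_MOL",
]

#: Conventional enthalpy cutoff separating physisorption from chemisorption.
CHEMISORPTION_THRESHOLD_KJ_MOL = 40.0


def gibbs_energy(k: float, temperature: float) -> float:
    """Standard Gibbs energy of adsorption, kJ/mol.

    ``dG0 = -R*T*ln(k)``; negative for k > 1 (spontaneous adsorption).
    """
    if not k > 0:
        raise DomainError("equilibrium constant must be positive")
    if not temperature > 0:
        raise ValidationError("temperature must be positive (kelvin)")
    return -R_GAS * temperature * math.log(k) / 1000.0


def classify_sorption(
    dh: float, threshold: float = CHEMISORPTION_THRESHOLD_KJ_MOL
) -> str:
    """Label the sorption regime from the enthalpy (kJ/mol).

    ``"chemisorption"`` iff ``dh > threshold`` (strict); the boundary value
    itself is classified as physisorption.
    """
    if not math.isfinite(dh):
        raise ValidationError("enthalpy must be finite")
    return "chemisorption" if dh > threshold else "physisorption"


@dataclass(frozen=True)
class ThermoResult:
    """Thermodynamic parameters from a van't Hoff analysis.

    ``dg`` holds the per-temperature Gibbs energies (kJ/mol), ``dh`` the
    enthalpy (kJ/mol), ``ds`` the entropy (kJ/(mol K)).
    """

    temperatures: np.ndarray
    kads: np.ndarray
    dg: np.ndarray
    dh: float
    ds: float
    r2_vant_hoff: float
    regime: str
    adsorbent_id: str = "unknown"

    def summary(self) -> str:
        lines = [f"van't Hoff analysis ({self.adsorbent_id})"]
        lines.append("-" * len(lines[0]))
        lines.append(f"{'T [K]':>8s} {'Kads':>10s} {'dG0 [kJ/mol]':>14s}")
        for t, k, g in zip(self.temperatures, self.kads, self.dg):
            lines.append(f"{t:8.1f} {k:10.4f} {g:14.3f}")
        lines.append(f"dH0 = {self.dh:.4f} kJ/mol")
        lines.append(f"dS0 = {self.ds:.4f} kJ/(mol K)")
        lines.append(f"R^2 (van't Hoff) = {self.r2_vant_hoff:.6f}")
        lines.append(f"regime: {self.regime}")
        return "\n".join(lines)

    def plot_vant_hoff(self, ax=None):
        """ln K against 1/T with the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        inv_t = 1.0 / self.temperatures
        ax.plot(inv_t, np.log(self.kads), "o", label="ln K")
        grid = np.linspace(inv_t.min(), inv_t.max(), 50)
        line = self.ds * 1000.0 / R_GAS - self.dh * 1000.0 / R_GAS * grid
        ax.plot(grid, line, "-", label="van't Hoff fit")
        ax.set_xlabel("1/T (1/K)")
        ax.set_ylabel("ln K")
        ax.legend()
        return ax


class VantHoff:
    """Van't Hoff model bound to a K(T) series; ``fit()`` performs the
    ordinary least-squares regression of ln K on 1/T."""

    def __init__(self, series: ThermoSeries):
        self.series = series

    def fit(self, threshold: float = CHEMISORPTION_THRESHOLD_KJ_MOL) -> ThermoResult:
        series = self.series
        inv_t = 1.0 / series.temperatures
        ln_k = np.log(series.kads)
        if len(series) == 2:
            # exact two-point line; linregress r is degenerate there
            slope = (ln_k[1] - ln_k[0]) / (inv_t[1] - inv_t[0])
            intercept = ln_k[0] - slope * inv_t[0]
            r2 = 1.0
        else:
            reg = stats.linregress(inv_t, ln_k)
            slope, intercept, r2 = reg.slope, reg.intercept, reg.rvalue**2
        dh = -R_GAS * slope / 1000.0
        ds = R_GAS * intercept / 1000.0
        dg = np.array([gibbs_energy(k, t) for k, t in zip(series.kads, series.temperatures)])
        return ThermoResult(
            temperatures=series.temperatures,
            kads=series.kads,
            dg=dg,
            dh=dh,
            ds=ds,
            r2_vant_hoff=r2,
            regime=classify_sorption(dh, threshold),
            adsorbent_id=series.adsorbent_id,
        )


def vant_hoff(series: ThermoSeries) -> ThermoResult:
    """Van't Hoff regression of a K(T) series (functional form)."""
    return VantHoff(series).fit()


def pzc_from_titration(curve: TitrationCurve) -> float:
    """Point of zero charge from a pH-drift curve.

    Returns the pH at the first zero crossing of delta_pH, linearly
    interpolated between the bracketing titration points.  An exact zero at
    a grid point is returned directly.
    """
    d = curve.delta_ph
    ph = curve.ph_initial
    zeros = np.nonzero(d == 0.0)[0]
    crossings = np.nonzero(d[:-1] * d[1:] < 0)[0]
    first_zero = zeros[0] if zeros.size else np.inf
    first_cross = crossings[0] if crossings.size else np.inf
    if not math.isfinite(min(first_zero, first_cross)):
        raise DomainError("no zero crossing in titration range")
    if first_zero <= first_cross:
        return float(ph[int(first_zero)])
    i = int(first_cross)
    return float(ph[i] + (ph[i + 1] - ph[i]) * (-d[i]) / (d[i + 1] - d[i]))
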
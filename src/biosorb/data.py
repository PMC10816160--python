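"""Typed containers for the experimental inputs of a biosorption study.

Each container validates its invariants on construction so that downstream
model code can assume well-formed data.  Arrays are stored as read-only
float64 ``numpy`` arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "IsothermDataset",
    "KineticTrace",
    "ThermoSeries",
    "TitrationCurve",
    "BatchConditions",
]


def _as_array(name: str, values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    arr.setflags(write=False)
    return arr


@dataclass(frozen=True)
class IsothermDataset:
    """Equilibrium (Ce, qe) pairs for one adsorbent at one temperature.

    Parameters
    ----------
    adsorbent_id : str
        Label of the sorbent (e.g. ``"OWP"``).
    temperature : float
        Absolute temperature in kelvin.
    ce : array-like
        Equilibrium solute concentrations, mg/L.
    qe : array-like
        Equilibrium adsorption capacities, mg/g.
    """

    adsorbent_id: str
    temperature: float
    ce: np.ndarray
    qe: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ce", _as_array("ce", self.ce))
        object.__setattr__(self, "qe", _as_array("qe", self.qe))
        if len(self.ce) != len(self.qe):
            raise ValidationError("ce and qe must have the same length")
        if len(self.ce) < 3:
            raise ValidationError("an isotherm needs at least 3 points")
        if np.any(self.ce < 0) or np.any(self.qe < 0):
            raise ValidationError("ce and qe must be nonnegative")
        if not self.temperature > 0:
            raise ValidationError("temperature must be positive (kelvin)")

    def __len__(self) -> int:
        return len(self.ce)


@dataclass(frozen=True)
class KineticTrace:
    """Time-resolved uptake (t, qt): t in minutes, qt in mg/g."""

    t: np.ndarray
    qt: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", _as_array("t", self.t))
        object.__setattr__(self, "qt", _as_array("qt", self.qt))
        if len(self.t) != len(self.qt):
            raise ValidationError("t and qt must have the same length")
        if np.any(self.t < 0):
            raise ValidationError("t must be nonnegative")
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError("t must be strictly increasing")
        if np.any(self.qt < 0):
            raise ValidationError("qt must be nonnegative")

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class ThermoSeries:
    """Equilibrium constants measured at several temperatures."""

    temperatures: np.ndarray
    kads: np.ndarray
    adsorbent_id: str = "unknown"

    def __post_init__(self) -> None:
        object.__setattr__(self, "temperatures", _as_array("temperatures", self.temperatures))
        object.__setattr__(self, "kads", _as_array("kads", self.kads))
        if len(self.temperatures) != len(self.kads):
            raise ValidationError("temperatures and kads must have the same length")
        if len(self.temperatures) < 2:
            raise ValidationError("need at least 2 temperatures")
        if np.any(self.temperatures <= 0):
            raise ValidationError("temperatures must be positive (kelvin)")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValidationError("temperatures must be strictly increasing")
        if np.any(self.kads <= 0):
            raise ValidationError("equilibrium constants must be positive")

    def __len__(self) -> int:
        return len(self.temperatures)


@dataclass(frozen=True)
class TitrationCurve:
    """pH-drift titration: initial pH and the drift delta_pH = pH_f - pH_i."""

    ph_initial: np.ndarray
    delta_ph: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ph_initial", _as_array("ph_initial", self.ph_initial))
        object.__setattr__(self, "delta_ph", _as_array("delta_ph", self.delta_ph))
        if len(self.ph_initial) != len(self.delta_ph):
            raise ValidationError("ph_initial and delta_ph must have the same length")
        if len(self.ph_initial) < 2:
            raise ValidationError("need at least 2 titration points")
        if np.any(np.diff(self.ph_initial) <= 0):
            raise ValidationError("ph_initial must be strictly increasing")

    def __len__(self) -> int:
        return len(self.ph_initial)


@dataclass(frozen=True)
class BatchConditions:
    """Batch experiment mass balance: C0 in mg/L, volume in L, sorbent mass in g."""

    c0: float
    volume: float
    mass: float

    def __post_init__(self) -> None:
        if self.c0 < 0:
            raise ValidationError("initial concentration must be nonnegative")
        if not self.volume > 0:
            raise ValidationError("volume must be positive")
        if not self.mass > 0:
            raise ValidationError("sorbent mass must be positive")

    @property
    def dose(self) -> float:
        """Sorbent dose m/V in g/L."""
        return self.mass / self.volume
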
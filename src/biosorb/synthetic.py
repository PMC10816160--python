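"""Seeded generators of synthetic study inputs.

Every generator draws from the closed-form forward models in
:mod:`biosorb.models` / :mod:`biosorb.thermo`, optionally perturbed by
multiplicative Gaussian noise (constant relative error, the defensible
default when capacities span an order of magnitude across datasets) or
additive Gaussian noise.  All randomness is controlled by the seed in
:class:`GeneratorSpec`, so generation is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import R_GAS
from .data import IsothermDataset, KineticTrace, ThermoSeries, TitrationCurve
from .exceptions import DomainError, ValidationError
from .models import (
    IPDParams,
    PFOParams,
    PSOParams,
    SLMRGParams,
    ipd_capacity,
    pfo_capacity,
    pso_capacity,
    slmrg_capacity,
)

__all__ = [
    "GeneratorSpec",
    "gen_isotherm",
    "gen_kinetics",
    "gen_ipd_three_regime",
    "gen_vant_hoff_series",
    "gen_pzc_curve",
]

_NOISE_MODELS = ("none", "multiplicative-gaussian", "additive-gaussian")


@dataclass(frozen=True)
class GeneratorSpec:
    """Noise model, noise level (relative sd for multiplicative noise,
    absolute sd for additive), seed and optional design grid."""

    seed: int = 0
    noise_model: str = "none"
    noise_sd: float = 0.0
    grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.noise_model not in _NOISE_MODELS:
            raise ValidationError(
                f"unknown noise model {self.noise_model!r}; choose from {_NOISE_MODELS}"
            )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be nonnegative")
        if self.grid is not None:
            grid = np.asarray(self.grid, dtype=float)
            if grid.ndim != 1 or grid.size == 0:
                raise ValidationError("grid must be a nonempty 1-D array")
            if np.any(np.diff(grid) <= 0):
                raise ValidationError("grid must be strictly increasing")
            grid.setflags(write=False)
            object.__setattr__(self, "grid", grid)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _apply_noise(values: np.ndarray, spec: GeneratorSpec) -> np.ndarray:
    if spec.noise_model == "none" or spec.noise_sd == 0.0:
        return values.copy()
    rng = spec.rng()
    eps = rng.normal(0.0, spec.noise_sd, size=values.shape)
    if spec.noise_model == "multiplicative-gaussian":
        noisy = values * (1.0 + eps)
    else:
        noisy = values + eps
    return np.clip(noisy, 0.0, None)


def default_ce_grid(params: SLMRGParams, n_points: int = 12) -> np.ndarray:
    """Log-spaced Ce design in [1, 0.8/b] mg/L (or [1, 100] at b = 0),
    mimicking typical batch isotherm designs."""
    upper = 0.8 / params.b if params.b > 0 else 100.0
    if upper <= 1.0:
        raise DomainError("co-volume bound leaves no room for the default grid")
    return np.geomspace(1.0, upper, n_points)


def gen_isotherm(
    params: SLMRGParams,
    temperature: float,
    spec: GeneratorSpec | None = None,
    adsorbent_id: str = "synthetic",
) -> IsothermDataset:
    """Synthetic equilibrium isotherm drawn from the SLMRG forward model."""
    spec = spec or GeneratorSpec()
    ce = spec.grid if spec.grid is not None else default_ce_grid(params)
    if params.b > 0 and np.any(ce >= 1.0 / params.b):
        raise DomainError(
            f"design grid violates the co-volume bound 1/b = {1.0 / params.b:.6g} mg/L"
        )
    qe = slmrg_capacity(ce, params, temperature)
    return IsothermDataset(
        adsorbent_id=adsorbent_id,
        temperature=temperature,
        ce=ce,
        qe=_apply_noise(np.asarray(qe), spec),
    )


def default_time_grid(n_points: int = 16, t_max: float = 480.0) -> np.ndarray:
    """Default kinetic sampling: dense early, sparse late (minutes)."""
    return np.unique(np.round(np.geomspace(2.0, t_max, n_points), 3))


def gen_kinetics(model: str, params, spec: GeneratorSpec | None = None) -> KineticTrace:
    """Synthetic uptake trace from an integrated kinetic forward model.

    ``model`` is one of ``"pfo"``, ``"pso"``, ``"ipd"`` with the matching
    parameter record.
    """
    spec = spec or GeneratorSpec()
    t = spec.grid if spec.grid is not None else default_time_grid()
    model = model.lower()
    if model == "pfo":
        if not isinstance(params, PFOParams):
            raise ValidationError("pfo generation needs PFOParams")
        qt = pfo_capacity(t, params)
    elif model == "pso":
        if not isinstance(params, PSOParams):
            raise ValidationError("pso generation needs PSOParams")
        qt = pso_capacity(t, params)
    elif model == "ipd":
        if not isinstance(params, IPDParams):
            raise ValidationError("ipd generation needs IPDParams")
        qt = ipd_capacity(t, params)
    else:
        raise ValidationError(f"unknown kinetic model {model!r}")
    return KineticTrace(t=t, qt=_apply_noise(np.asarray(qt), spec))


def gen_ipd_three_regime(
    segments: tuple[IPDParams, IPDParams, IPDParams],
    breakpoints: tuple[float, float],
    spec: GeneratorSpec | None = None,
    n_per_segment: int = 5,
    t_max: float = 480.0,
) -> KineticTrace:
    """Piecewise Weber-Morris trace with three diffusion regimes.

    ``breakpoints`` are the times (min) at which the second and third
    regime begin; each regime follows its own ``qt = kid*sqrt(t) + c`` law,
    sampled at ``n_per_segment`` points.
    """
    spec = spec or GeneratorSpec()
    b1, b2 = breakpoints
    if not 0 < b1 < b2 < t_max:
        raise ValidationError("breakpoints must satisfy 0 < b1 < b2 < t_max")
    edges = [(1.0, b1), (b1 * 1.05, b2), (b2 * 1.05, t_max)]
    ts, qts = [], []
    for (lo, hi), seg in zip(edges, segments):
        t_seg = np.linspace(lo, hi, n_per_segment)
        ts.append(t_seg)
        qts.append(ipd_capacity(t_seg, seg))
    t = np.concatenate(ts)
    qt = np.concatenate(qts)
    return KineticTrace(t=t, qt=_apply_noise(qt, spec))


def gen_vant_hoff_series(
    dh: float, ds: float, temperatures, adsorbent_id: str = "synthetic"
) -> ThermoSeries:
    """Exact van't Hoff K(T) series from enthalpy (kJ/mol) and entropy
    (kJ/(mol K)): ``K = exp(ds*1000/R - dh*1000/(R*T))``."""
    temps = np.asarray(temperatures, dtype=float)
    k = np.exp(ds * 1000.0 / R_GAS - dh * 1000.0 / (R_GAS * temps))
    return ThermoSeries(temperatures=temps, kads=k, adsorbent_id=adsorbent_id)


def gen_pzc_curve(
    true_pzc: float,
    spec: GeneratorSpec | None = None,
    amplitude: float = 1.5,
    width: float = 2.0,
) -> TitrationCurve:
    """Smooth monotone pH-drift curve with its unique zero at ``true_pzc``.

    The drift follows ``delta_pH = amplitude * tanh((pzc - pH_i)/width)``,
    the sigmoidal shape pH-drift experiments produce: positive drift below
    the point of zero charge, negative above.
    """
    spec = spec or GeneratorSpec()
    ph = spec.grid if spec.grid is not None else np.arange(2.0, 12.01, 0.5)
    if not (ph[0] < true_pzc < ph[-1]):
        raise DomainError(
            f"true_pzc = {true_pzc} outside the titration grid [{ph[0]}, {ph[-1]}]"
        )
    delta = amplitude * np.tanh((true_pzc - ph) / width)
    if spec.noise_model != "none" and spec.noise_sd > 0:
        delta = delta + spec.rng().normal(0.0, spec.noise_sd, size=delta.shape)
    return TitrationCurve(ph_initial=ph, delta_ph=delta)
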
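"""Parameter estimation for the equilibrium and kinetic models.

The module follows the model/results convention of statistical packages:
a model object is built from a dataset, its :meth:`fit` returns a results
object carrying the estimates, goodness-of-fit diagnostics and a
``summary()`` table.  Thin functional wrappers (``fit_slmrg``,
``fit_pso_linear``, ...) expose the same operations for script use.

Nonlinear fits are multi-start trust-region least squares: starting points
are drawn by seeded Latin-hypercube sampling over the parameter bounds
(log-spaced for the scale parameters), augmented with data-driven heuristic
starts, and the best local solution is returned.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.stats import qmc

from .data import IsothermDataset, KineticTrace
from .exceptions import ConvergenceError, DomainError, ValidationError
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
    "FitOptions",
    "FitResult",
    "IPDSegmentation",
    "SLMRG",
    "KineticModel",
    "goodness",
    "fit_slmrg",
    "fit_pfo_linear",
    "fit_pso_linear",
    "fit_kinetics_nonlinear",
    "fit_ipd_segments",
]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class FitOptions:
    """Options controlling a nonlinear least-squares fit."""

    n_starts: int = 32
    bounds: dict | None = None
    seed: int = 0
    loss: str = "least-squares"

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValidationError("n_starts must be at least 1")
        if self.loss != "least-squares":
            raise ValidationError(f"unsupported loss {self.loss!r}")


@dataclass(frozen=True)
class FitResult:
    """Estimates plus diagnostics from one model fit."""

    params: object
    r2: float
    rmse: float
    n_obs: int
    converged: bool
    starts_tried: int = 1
    residuals: np.ndarray | None = None
    notes: tuple[str, ...] = ()
    model_name: str = ""

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        lines = [f"{self.model_name or type(self.params).__name__} fit"]
        lines.append("-" * len(lines[0]))
        if self.params is not None:
            for name, value in vars(self.params).items():
                lines.append(f"{name:>10s} : {value:.6g}")
        lines.append(f"{'R^2':>10s} : {self.r2:.6f}")
        lines.append(f"{'RMSE':>10s} : {self.rmse:.6g}")
        lines.append(f"{'n_obs':>10s} : {self.n_obs}")
        lines.append(f"{'converged':>10s} : {self.converged}")
        if self.starts_tried > 1:
            lines.append(f"{'starts':>10s} : {self.starts_tried}")
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)


def goodness(observed, predicted, n_params: int) -> tuple[float, float]:
    """Coefficient of determination and root-mean-square error.

    ``r2 = 1 - SSE/SST`` with SST about the observed mean and
    ``rmse = sqrt(SSE/N)`` (no degrees-of-freedom correction).  A series
    with zero variance has no defined r2; NaN is returned with a warning.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValidationError("observed and predicted must have the same shape")
    if obs.size < 2:
        raise ValidationError("need at least 2 observations")
    if obs.size < n_params + 1:
        raise ValidationError("need more observations than free parameters")
    sse = float(np.sum((obs - pred) ** 2))
    sst = float(np.sum((obs - obs.mean()) ** 2))
    rmse = math.sqrt(sse / obs.size)
    if sst == 0.0:
        warnings.warn("observed series is constant: r2 undefined", stacklevel=2)
        return (float("nan"), rmse)
    return (1.0 - sse / sst, rmse)


# ---------------------------------------------------------------------------
# SLMRG isotherm fitting
# ---------------------------------------------------------------------------

_SLMRG_NAMES = ("n", "nm", "a", "b", "w")


class SLMRG:
    """SLMRG isotherm model bound to an equilibrium dataset.

    Parameters
    ----------
    data : IsothermDataset
        Equilibrium (Ce, qe) pairs with their temperature.

    Examples
    --------
    >>> model = SLMRG(dataset)            # doctest: +SKIP
    >>> res = model.fit()                 # doctest: +SKIP
    >>> print(res.summary())              # doctest: +SKIP
    """

    def __init__(self, data: IsothermDataset):
        if len(data) < 6:
            raise ValidationError("SLMRG fitting needs at least 6 isotherm points")
        self.data = data

    # -- bounds -------------------------------------------------------------
    def default_bounds(self) -> dict[str, tuple[float, float]]:
        """Default box constraints for the five parameters.

        The steric exponent is allowed below 1 (composite biosorbents show
        n < 1 when one molecule bridges several sites) and the co-volume is
        capped at ``0.9/max(Ce)`` so every observed concentration stays
        inside the model domain.
        """
        ce_max = float(np.max(self.data.ce))
        return {
            "n": (0.1, 10.0),
            "nm": (1e-3, 1e4),
            "a": (0.0, 1e3),
            "b": (0.0, 0.9 / ce_max),
            "w": (1e-3, 1e4),
        }

    def predict(self, params: SLMRGParams, ce=None):
        """Model capacity at ``ce`` (defaults to the observed grid)."""
        if ce is None:
            ce = self.data.ce
        return slmrg_capacity(ce, params, self.data.temperature)

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        n, nm, a, b, w = x
        ce, temp = self.data.ce, self.data.temperature
        bc = b * ce
        safe = 1.0 - bc
        # beta in the tabulated unit system of a (1e-23 J L/mg)
        two_a_beta = 2.0 * a / (1.380649 * temp)
        with np.errstate(all="ignore"):
            f = ce / safe * np.exp(bc / safe) * np.exp(-two_a_beta * ce)
            ratio = np.where(f > 0, w / f, np.inf)
            qhat = n * nm / (1.0 + ratio**n)
        qhat = np.where(np.isfinite(qhat), qhat, 0.0)
        return qhat - self.data.qe

    def _heuristic_starts(self, bounds: dict) -> list[np.ndarray]:
        ce, qe = self.data.ce, self.data.qe
        qsat0 = max(float(np.max(qe)) * 1.05, 1e-6)
        half = 0.5 * qsat0
        # concentration nearest the half-saturation capacity
        w0 = float(ce[np.argmin(np.abs(qe - half))])
        w0 = min(max(w0, bounds["w"][0] * 1.01), bounds["w"][1] * 0.99)
        starts = []
        for n0 in (0.5, 1.0, 2.0, 3.0):
            for a0, b0 in ((0.0, 0.0), (10.0, 0.5 * bounds["b"][1])):
                x = np.array([n0, qsat0 / n0, a0, b0, w0])
                starts.append(self._clip_to_bounds(x, bounds))
        return starts

    @staticmethod
    def _clip_to_bounds(x: np.ndarray, bounds: dict) -> np.ndarray:
        lo = np.array([bounds[k][0] for k in _SLMRG_NAMES])
        hi = np.array([bounds[k][1] for k in _SLMRG_NAMES])
        return np.clip(x, lo, hi)

    def _lhs_starts(self, bounds: dict, n_starts: int, seed: int) -> list[np.ndarray]:
        sampler = qmc.LatinHypercube(d=5, seed=seed)
        u = sampler.random(n_starts)
        starts = []
        for row in u:
            x = np.empty(5)
            # linear in n, a, b; log-uniform in the scale parameters nm, w
            x[0] = bounds["n"][0] + row[0] * (bounds["n"][1] - bounds["n"][0])
            x[1] = 10 ** (
                math.log10(max(bounds["nm"][0], 1e-2))
                + row[1] * (math.log10(bounds["nm"][1]) - math.log10(max(bounds["nm"][0], 1e-2)))
            )
            x[2] = bounds["a"][0] + row[2] * (bounds["a"][1] - bounds["a"][0])
            x[3] = bounds["b"][0] + row[3] * (bounds["b"][1] - bounds["b"][0])
            x[4] = 10 ** (
                math.log10(max(bounds["w"][0], 1e-2))
                + row[4] * (math.log10(bounds["w"][1]) - math.log10(max(bounds["w"][0], 1e-2)))
            )
            starts.append(x)
        return starts

    def fit(self, options: FitOptions | None = None) -> "SLMRGResults":
        """Multi-start bounded least-squares fit of the five parameters."""
        options = options or FitOptions()
        bounds = dict(self.default_bounds())
        if options.bounds:
            bounds.update(options.bounds)
        lo = np.array([bounds[k][0] for k in _SLMRG_NAMES])
        hi = np.array([bounds[k][1] for k in _SLMRG_NAMES])

        starts = self._heuristic_starts(bounds)
        n_lhs = max(options.n_starts - len(starts), 0)
        if n_lhs:
            starts += self._lhs_starts(bounds, n_lhs, options.seed)
        starts = starts[: max(options.n_starts, len(self._heuristic_starts(bounds)))]

        best = None
        n_ok = 0
        failures = []
        for x0 in starts:
            try:
                sol = optimize.least_squares(
                    self._residuals,
                    x0,
                    bounds=(lo, hi),
                    method="trf",
                    x_scale="jac",
                    xtol=1e-14,
                    ftol=1e-14,
                    gtol=1e-14,
                    max_nfev=2000,
                )
            except Exception as exc:  # pragma: no cover - defensive
                failures.append(str(exc))
                continue
            if not sol.success:
                failures.append(sol.message)
                continue
            n_ok += 1
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise ConvergenceError(
                f"all {len(starts)} starts failed to converge; last messages: "
                + "; ".join(failures[-3:])
            )

        params = SLMRGParams(*best.x)
        pred = self.predict(params)
        r2, rmse = goodness(self.data.qe, pred, n_params=5)
        return SLMRGResults(
            params=params,
            r2=r2,
            rmse=rmse,
            n_obs=len(self.data),
            converged=True,
            starts_tried=len(starts),
            residuals=pred - self.data.qe,
            model_name=f"SLMRG isotherm ({self.data.adsorbent_id}, {self.data.temperature:g} K)",
            model=self,
        )


@dataclass(frozen=True)
class SLMRGResults(FitResult):
    """SLMRG fit results; adds prediction and plotting on top of FitResult."""

    model: SLMRG | None = None

    @property
    def qsat(self) -> float:
        """Saturation capacity n*Nm implied by the fitted parameters, mg/g."""
        return self.params.n * self.params.nm

    def predict(self, ce=None):
        return self.model.predict(self.params, ce)

    def plot_fit(self, ax=None):
        """Observed points and fitted curve on a dense Ce grid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        data = self.model.data
        grid = np.linspace(0, float(np.max(data.ce)), 200)
        ax.plot(data.ce, data.qe, "o", label="observed")
        ax.plot(grid, self.predict(grid), "-", label="SLMRG fit")
        ax.set_xlabel("Ce (mg/L)")
        ax.set_ylabel("qe (mg/g)")
        ax.legend()
        return ax

    def summary(self) -> str:
        base = super().summary()
        return base + f"\n{'Qsat':>10s} : {self.qsat:.6g} mg/g"


def fit_slmrg(data: IsothermDataset, options: FitOptions | None = None) -> SLMRGResults:
    """Fit the SLMRG isotherm to an equilibrium dataset (functional form)."""
    return SLMRG(data).fit(options)


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------


def fit_pfo_linear(trace: KineticTrace, qe_exp: float) -> FitResult:
    """Pseudo-first-order fit via the log-linearization.

    Regresses ``log10(qe_exp - qt)`` on ``t``; the rate is ``k1 =
    -ln(10) * slope`` and the intercept gives the model plateau.  The
    experimental plateau ``qe_exp`` must exceed every observed ``qt``.
    """
    bad = np.nonzero(trace.qt >= qe_exp)[0]
    if bad.size:
        raise DomainError(
            f"qt >= qe_exp at point index {int(bad[0])} "
            f"(qt={trace.qt[bad[0]]:g}, qe_exp={qe_exp:g}); "
            "the log-linearization is undefined there"
        )
    y = np.log10(qe_exp - trace.qt)
    reg = stats.linregress(trace.t, y)
    k1 = -LN10 * reg.slope
    qe_fit = 10.0**reg.intercept
    if k1 <= 0:
        raise ConvergenceError("nonpositive rate from the log-linearization: trace is not PFO-like")
    params = PFOParams(qe=qe_fit, k1=k1)
    return FitResult(
        params=params,
        r2=reg.rvalue**2,
        rmse=math.sqrt(float(np.mean((y - (reg.intercept + reg.slope * trace.t)) ** 2))),
        n_obs=len(trace),
        converged=True,
        residuals=y - (reg.intercept + reg.slope * trace.t),
        notes=("r2 and rmse refer to the linearized regression",),
        model_name="PFO (linearized)",
    )


def fit_pso_linear(trace: KineticTrace) -> FitResult:
    """Pseudo-second-order fit via the reciprocal linearization.

    Regresses ``t/qt`` on ``t``; slope gives ``qe = 1/slope`` and the
    intercept gives ``k2 = slope^2 / intercept``.  Exact on noiseless PSO
    data (the linearization is lossless).
    """
    bad = np.nonzero(trace.qt <= 0)[0]
    if bad.size:
        raise DomainError(f"qt must be positive for PSO linearization (point index {int(bad[0])})")
    if np.any(trace.t <= 0):
        raise DomainError("t must be strictly positive for the t/qt linearization")
    y = trace.t / trace.qt
    reg = stats.linregress(trace.t, y)
    if reg.slope <= 0:
        raise ConvergenceError("nonpositive slope in t/qt regression: trace is not PSO-like")
    notes = ("r2 and rmse refer to the linearized regression",)
    scale = float(np.max(np.abs(y)))
    if abs(reg.intercept) <= 1e-12 * max(scale, 1.0):
        # constant qt: instantaneous equilibrium, rate unidentified
        params = PSOParams(qe=1.0 / reg.slope, k2=math.inf)
        notes += ("degenerate: zero intercept (instantaneous equilibrium, k2 unidentified)",)
    else:
        if reg.intercept < 0:
            raise ConvergenceError("negative intercept in t/qt regression: trace is not PSO-like")
        params = PSOParams(qe=1.0 / reg.slope, k2=reg.slope**2 / reg.intercept)
    return FitResult(
        params=params,
        r2=reg.rvalue**2,
        rmse=math.sqrt(float(np.mean((y - (reg.intercept + reg.slope * trace.t)) ** 2))),
        n_obs=len(trace),
        converged=True,
        residuals=y - (reg.intercept + reg.slope * trace.t),
        notes=notes,
        model_name="PSO (linearized)",
    )


_KINETIC_FORWARD: dict[str, Callable] = {
    "pfo": lambda t, x: x[0] * (1.0 - np.exp(-x[1] * t)),
    "pso": lambda t, x: x[0] * x[0] * x[1] * t / (1.0 + x[0] * x[1] * t),
}


class KineticModel:
    """Integrated-form kinetic model (``"pfo"``, ``"pso"`` or ``"ipd"``)
    bound to an uptake trace."""

    def __init__(self, trace: KineticTrace, kind: str):
        kind = kind.lower()
        if kind not in ("pfo", "pso", "ipd"):
            raise ValidationError(f"unknown kinetic model {kind!r}")
        if len(trace) < 4:
            raise ValidationError("kinetic fitting needs at least 4 points")
        self.trace = trace
        self.kind = kind

    def predict(self, params, t=None):
        t = self.trace.t if t is None else t
        if self.kind == "pfo":
            return pfo_capacity(t, params)
        if self.kind == "pso":
            return pso_capacity(t, params)
        return ipd_capacity(t, params)

    def fit(self, options: FitOptions | None = None) -> FitResult:
        options = options or FitOptions()
        trace = self.trace
        if self.kind == "ipd":
            # linear in (kid, c): closed-form least squares
            reg = stats.linregress(np.sqrt(trace.t), trace.qt)
            params = IPDParams(kid=max(reg.slope, 0.0), c=reg.intercept)
            pred = self.predict(params)
            r2, rmse = goodness(trace.qt, pred, n_params=2)
            return FitResult(
                params=params, r2=r2, rmse=rmse, n_obs=len(trace), converged=True,
                residuals=pred - trace.qt, model_name="IPD (Weber-Morris)",
            )

        forward = _KINETIC_FORWARD[self.kind]
        qe0 = max(float(np.max(trace.qt)) * 1.02, 1e-6)
        # half-saturation heuristics for the rate
        t_half = float(np.interp(0.5 * qe0, trace.qt, trace.t)) or float(trace.t[len(trace) // 2])
        t_half = max(t_half, float(trace.t[trace.t > 0][0]) if np.any(trace.t > 0) else 1.0)
        if self.kind == "pfo":
            rate0 = math.log(2.0) / t_half
        else:
            rate0 = 1.0 / (qe0 * t_half)
        starts = [np.array([qe0, rate0])]
        rng = np.random.default_rng(options.seed)
        for _ in range(max(options.n_starts - 1, 0)):
            starts.append(np.array([
                qe0 * 10 ** rng.uniform(-0.3, 0.3),
                rate0 * 10 ** rng.uniform(-2.0, 2.0),
            ]))

        best = None
        failures = []
        for x0 in starts:
            try:
                sol = optimize.least_squares(
                    lambda x: forward(trace.t, x) - trace.qt,
                    x0,
                    bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                    method="trf",
                    x_scale="jac",
                    xtol=1e-15, ftol=1e-15, gtol=1e-15,
                    max_nfev=2000,
                )
            except Exception as exc:  # pragma: no cover - defensive
                failures.append(str(exc))
                continue
            if not sol.success:
                failures.append(sol.message)
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise ConvergenceError(
                f"all {len(starts)} starts failed: " + "; ".join(failures[-3:])
            )
        if self.kind == "pfo":
            params = PFOParams(qe=best.x[0], k1=best.x[1])
        else:
            params = PSOParams(qe=best.x[0], k2=best.x[1])
        pred = self.predict(params)
        r2, rmse = goodness(trace.qt, pred, n_params=2)
        return FitResult(
            params=params, r2=r2, rmse=rmse, n_obs=len(trace), converged=True,
            starts_tried=len(starts), residuals=pred - trace.qt,
            model_name=f"{self.kind.upper()} (nonlinear)",
        )


def fit_kinetics_nonlinear(
    model: str, trace: KineticTrace, options: FitOptions | None = None
) -> FitResult:
    """Nonlinear least-squares fit of an integrated kinetic model."""
    return KineticModel(trace, model).fit(options)


# ---------------------------------------------------------------------------
# Piecewise Weber-Morris (multi-regime intraparticle diffusion)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IPDSegmentation:
    """Piecewise Weber-Morris fit: successive diffusion regimes in sqrt(t).

    ``breakpoints`` are the data indices at which a new segment starts
    (empty for a single segment); ``through_origin`` records whether the
    first segment's intercept is within ``origin_tol`` of zero, the
    conventional check for film-diffusion control.
    """

    segments: tuple[IPDParams, ...]
    breakpoints: tuple[int, ...]
    sse: float
    r2: float
    through_origin: bool
    origin_tol: float

    def summary(self) -> str:
        lines = [f"Weber-Morris segmentation ({len(self.segments)} regimes)"]
        for i, seg in enumerate(self.segments, 1):
            lines.append(f"  segment {i}: kid={seg.kid:.6g} mg/(g min^0.5), c={seg.c:.6g} mg/g")
        lines.append(f"  breakpoints at indices {list(self.breakpoints)}")
        lines.append(f"  SSE={self.sse:.6g}, R^2={self.r2:.6f}")
        lines.append(
            f"  first segment through origin: {self.through_origin} (|c| tol {self.origin_tol:g})"
        )
        return "\n".join(lines)


def _segment_ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and SSE of an OLS line through (x, y)."""
    if len(x) == 2 and x[1] == x[0]:  # pragma: no cover - guarded upstream
        raise DomainError("degenerate segment")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return float(slope), float(intercept), float(resid @ resid)


def fit_ipd_segments(
    trace: KineticTrace, n_segments: int, origin_tol: float = 0.5
) -> IPDSegmentation:
    """Piecewise-linear Weber-Morris fit with exhaustively searched breakpoints.

    The trace is split into ``n_segments`` contiguous runs of points (each
    with at least 2 points); every admissible split is scored by the total
    SSE of per-segment OLS lines in sqrt(t), and the minimizer is returned
    (ties broken in favour of the earliest breakpoints).  Successive regimes
    are conventionally read as film diffusion, intraparticle diffusion and
    the equilibrium plateau.
    """
    if n_segments not in (1, 2, 3):
        raise ValidationError("n_segments must be 1, 2 or 3")
    npts = len(trace)
    if npts < 2 * n_segments + 1:
        raise ValidationError(
            f"{npts} points cannot support {n_segments} segments "
            f"(need at least {2 * n_segments + 1})"
        )
    x = np.sqrt(trace.t)
    y = trace.qt

    best: tuple[float, tuple[int, ...]] | None = None
    # breakpoints = indices where a new segment begins
    for cuts in itertools.combinations(range(2, npts - 1), n_segments - 1):
        edges = (0, *cuts, npts)
        if any(edges[i + 1] - edges[i] < 2 for i in range(n_segments)):
            continue
        sse = 0.0
        for i in range(n_segments):
            sse += _segment_ols(x[edges[i]:edges[i + 1]], y[edges[i]:edges[i + 1]])[2]
        if best is None or sse < best[0] - 1e-15:
            best = (sse, cuts)
    assert best is not None
    sse, cuts = best
    edges = (0, *cuts, npts)
    segments = []
    pred = np.empty_like(y)
    for i in range(n_segments):
        seg_x = x[edges[i]:edges[i + 1]]
        seg_y = y[edges[i]:edges[i + 1]]
        slope, intercept, _ = _segment_ols(seg_x, seg_y)
        segments.append(IPDParams(kid=max(slope, 0.0), c=intercept))
        pred[edges[i]:edges[i + 1]] = slope * seg_x + intercept
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    return IPDSegmentation(
        segments=tuple(segments),
        breakpoints=tuple(cuts),
        sse=sse,
        r2=r2,
        through_origin=abs(segments[0].c) <= origin_tol,
        origin_tol=origin_tol,
    )
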
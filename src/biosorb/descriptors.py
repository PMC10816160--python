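"""Post-processing of quantum-chemistry outputs into reactivity descriptors.

Three independent analyses are covered, all operating on user-supplied
numbers (no electronic-structure calculation is run here):

* **Global conceptual-DFT descriptors** from frontier-orbital energies:
  gap, chemical potential, electronegativity, hardness, electrophilicity
  and the maximum-charge-transfer index.
* **Sigma-profile regions**: partition of a COSMO-RS screening-charge
  histogram into hydrogen-bond-donor, nonpolar and hydrogen-bond-acceptor
  areas at the conventional +-0.0075 e/A^2 thresholds.
* **QTAIM bond-critical-point classification** from the electron density,
  its Laplacian and the kinetic/potential energy densities at the BCP.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, ValidationError

__all__ = [
    "OrbitalRecord",
    "DescriptorSet",
    "SigmaProfile",
    "SigmaRegions",
    "BcpRecord",
    "BcpClassification",
    "global_descriptors",
    "charge_transfer",
    "sigma_regions",
    "classify_bcp",
    "SIGMA_NONPOLAR_EDGE",
]

#: Conventional sigma threshold (e/A^2) separating the nonpolar region from
#: the hydrogen-bond-donor (sigma < -edge) and acceptor (sigma > +edge) tails.
SIGMA_NONPOLAR_EDGE = 0.0075


@dataclass(frozen=True)
class OrbitalRecord:
    """Frontier-orbital energies of one species, in eV."""

    species_id: str
    e_homo: float
    e_lumo: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.e_homo) and math.isfinite(self.e_lumo)):
            raise ValidationError("orbital energies must be finite")
        if self.e_lumo < self.e_homo:
            raise ValidationError(
                f"{self.species_id}: E_LUMO ({self.e_lumo}) below E_HOMO ({self.e_homo})"
            )


@dataclass(frozen=True)
class DescriptorSet:
    """Global reactivity descriptors of one species (all in eV except the
    dimensionless charge-transfer index).

    ``gap = E_LUMO - E_HOMO``; ``mu = (E_HOMO + E_LUMO)/2`` is the chemical
    potential; ``chi = -mu`` the electronegativity; ``eta = gap/2`` the
    hardness; ``omega = mu^2/(2 eta)`` the electrophilicity index; and
    ``dn_max = chi/eta`` the single-species maximum charge transfer.
    """

    species_id: str
    gap: float
    mu: float
    chi: float
    eta: float
    omega: float
    dn_max: float

    def summary(self) -> str:
        return (
            f"{self.species_id}: gap={self.gap:.3f} eV, mu={self.mu:.3f} eV, "
            f"chi={self.chi:.3f} eV, eta={self.eta:.3f} eV, "
            f"omega={self.omega:.3f} eV, dNmax={self.dn_max:.3f}"
        )


def global_descriptors(rec: OrbitalRecord) -> DescriptorSet:
    """Conceptual-DFT descriptors from one pair of frontier-orbital energies.

    All quantities are computed from the unrounded inputs.  A vanishing
    gap leaves the hardness zero and the electrophilicity undefined.
    """
    gap = rec.e_lumo - rec.e_homo
    if gap == 0:
        raise DomainError(
            f"{rec.species_id}: degenerate frontier orbitals (zero gap); "
            "hardness-based descriptors are undefined"
        )
    mu = 0.5 * (rec.e_homo + rec.e_lumo)
    eta = 0.5 * gap
    return DescriptorSet(
        species_id=rec.species_id,
        gap=gap,
        mu=mu,
        chi=-mu,
        eta=eta,
        omega=mu * mu / (2.0 * eta),
        dn_max=(-mu) / eta,
    )


def charge_transfer(
    donor: DescriptorSet, acceptor: DescriptorSet, variant: str = "single"
) -> float:
    """Maximum-charge-transfer index between a donor and an acceptor.

    Two conventions coexist in the descriptor literature and both are
    offered:

    * ``"pairwise"`` — the two-species flow at electronegativity
      equalization, ``(chi_acceptor - chi_donor) / (2*(eta_acceptor +
      eta_donor))``.
    * ``"single"`` — the one-species saturation value ``chi/eta`` of the
      *acceptor*, i.e. how much charge the acceptor could take from a
      perfect donor.  This is the convention that published descriptor
      tables for these sorbent systems follow.
    """
    if not (donor.eta > 0 and acceptor.eta > 0):
        raise DomainError("hardness must be positive for charge-transfer indices")
    if variant == "pairwise":
        return (acceptor.chi - donor.chi) / (2.0 * (acceptor.eta + donor.eta))
    if variant == "single":
        return acceptor.chi / acceptor.eta
    raise ValidationError(f"unknown charge-transfer variant {variant!r}")


# ---------------------------------------------------------------------------
# sigma profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SigmaProfile:
    """COSMO-RS sigma profile: screening-charge density grid (e/A^2) and
    the surface-area density p(sigma) at each grid point (A^2)."""

    sigma: np.ndarray
    p_sigma: np.ndarray

    def __post_init__(self) -> None:
        sig = np.asarray(self.sigma, dtype=float)
        p = np.asarray(self.p_sigma, dtype=float)
        if sig.ndim != 1 or p.ndim != 1 or len(sig) != len(p):
            raise ValidationError("sigma and p_sigma must be 1-D of equal length")
        if len(sig) < 2:
            raise ValidationError("need at least 2 grid points")
        if not (np.all(np.isfinite(sig)) and np.all(np.isfinite(p))):
            raise ValidationError("profile contains non-finite values")
        if np.any(np.diff(sig) <= 0):
            raise ValidationError("sigma grid must be strictly increasing")
        if np.any(p < 0):
            raise ValidationError("p_sigma must be nonnegative")
        sig.setflags(write=False)
        p.setflags(write=False)
        object.__setattr__(self, "sigma", sig)
        object.__setattr__(self, "p_sigma", p)


@dataclass(frozen=True)
class SigmaRegions:
    """Areas (A^2) and area fractions of the three sigma-profile regions."""

    area_hbd: float
    area_nonpolar: float
    area_hba: float
    frac_hbd: float
    frac_nonpolar: float
    frac_hba: float

    @property
    def total_area(self) -> float:
        return self.area_hbd + self.area_nonpolar + self.area_hba


def _area_between(sigma: np.ndarray, p: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal area of p(sigma) restricted to [lo, hi]."""
    if hi <= sigma[0] or lo >= sigma[-1]:
        return 0.0
    lo = max(lo, float(sigma[0]))
    hi = min(hi, float(sigma[-1]))
    grid = np.unique(np.concatenate([sigma[(sigma > lo) & (sigma < hi)], [lo, hi]]))
    vals = np.interp(grid, sigma, p)
    return float(np.trapezoid(vals, grid))


def sigma_regions(profile: SigmaProfile) -> SigmaRegions:
    """Partition a sigma profile into HBD / nonpolar / HBA areas.

    The hydrogen-bond-donor region is ``sigma < -0.0075`` e/A^2, the
    nonpolar region ``|sigma| <= 0.0075`` and the acceptor region
    ``sigma > +0.0075``; profile tails beyond +-0.03 are assigned to the
    adjacent polar region so that the three fractions always sum to one.
    """
    sig, p = profile.sigma, profile.p_sigma
    edge = SIGMA_NONPOLAR_EDGE
    a_hbd = _area_between(sig, p, -np.inf, -edge)
    a_np = _area_between(sig, p, -edge, edge)
    a_hba = _area_between(sig, p, edge, np.inf)
    total = a_hbd + a_np + a_hba
    if total <= 0:
        warnings.warn("sigma profile has zero total area: fractions undefined", stacklevel=2)
        nan = float("nan")
        return SigmaRegions(a_hbd, a_np, a_hba, nan, nan, nan)
    return SigmaRegions(
        a_hbd, a_np, a_hba, a_hbd / total, a_np / total, a_hba / total
    )


# ---------------------------------------------------------------------------
# QTAIM bond critical points
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BcpRecord:
    """QTAIM descriptors at one bond critical point, in atomic units:
    electron density rho, its Laplacian, kinetic energy density G(rc) >= 0
    and potential energy density V(rc) <= 0."""

    bcp_id: str
    rho: float
    lap_rho: float
    g: float
    v: float

    def __post_init__(self) -> None:
        if self.g < 0:
            raise ValidationError(f"{self.bcp_id}: kinetic energy density must be >= 0")
        if self.v > 0:
            raise ValidationError(f"{self.bcp_id}: potential energy density must be <= 0")


@dataclass(frozen=True)
class BcpClassification:
    """Classification of one BCP: total energy density H = G + V, the
    covalency ratio G/|V| and the interaction class."""

    bcp_id: str
    h: float
    ratio: float
    label: str


def classify_bcp(rec: BcpRecord) -> BcpClassification:
    """Classify the bonding character at a bond critical point.

    * ``lap_rho < 0`` — shared-shell (covalent) interaction.
    * ``lap_rho >= 0`` and ``G/|V| < 1`` (equivalently H < 0) — closed-shell
      interaction with partially covalent character.
    * ``lap_rho >= 0`` and ``G/|V| >= 1`` — weak, purely noncovalent
      closed-shell interaction.

    The sign of the total energy density H(rc) serves as tiebreaker,
    consistent with common QTAIM practice; G/|V| = 1 (H = 0) is classified
    as noncovalent.
    """
    if rec.v == 0:
        raise DomainError(f"{rec.bcp_id}: zero potential energy density, G/|V| undefined")
    h = rec.g + rec.v
    ratio = rec.g / abs(rec.v)
    if rec.lap_rho < 0:
        label = "covalent"
    elif ratio < 1.0 and h < 0:
        label = "partially_covalent"
    else:
        label = "noncovalent_weak"
    return BcpClassification(bcp_id=rec.bcp_id, h=h, ratio=ratio, label=label)
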
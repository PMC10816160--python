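"""Delimited-text readers and writers for the study's tabular formats.

All formats are headered CSV/TSV (comma default, tab accepted, decimal
point only).  Each schema maps a fixed header onto one of the typed
containers; validation failures report the offending row.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from .data import IsothermDataset, KineticTrace, ThermoSeries, TitrationCurve
from .descriptors import BcpRecord, OrbitalRecord, SigmaProfile
from .exceptions import SchemaError, ValidationError

__all__ = ["SCHEMAS", "read_table", "write_table"]

#: schema name -> required column headers, in order
SCHEMAS: dict[str, tuple[str, ...]] = {
    "isotherm": ("Ce_mg_L", "qe_mg_g"),
    "kinetics": ("t_min", "qt_mg_g"),
    "thermo": ("T_K", "K_ads"),
    "titration": ("pHi", "delta_pH"),
    "orbitals": ("species", "E_HOMO_eV", "E_LUMO_eV"),
    "sigma": ("sigma_eA2", "p_sigma"),
    "bcp": ("bcp_id", "rho", "lap_rho", "G", "V"),
}

_TEXT_COLUMNS = {"species", "bcp_id"}


def _read_frame(path, schema: str) -> pd.DataFrame:
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; choose from {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise SchemaError(f"{path}: file is empty")
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    except csv.Error as exc:
        raise SchemaError(f"{path}: cannot parse delimited text ({exc})") from None
    expected = SCHEMAS[schema]
    if tuple(df.columns) != expected:
        raise SchemaError(
            f"{path}: header {tuple(df.columns)} does not match the "
            f"{schema!r} schema {expected}"
        )
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    for col in expected:
        if col in _TEXT_COLUMNS:
            continue
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna()].tolist()
        if bad:
            raise SchemaError(
                f"{path}: non-numeric value in column {col!r} at data row(s) "
                f"{[i + 1 for i in bad]}"
            )
        df[col] = numeric.astype(float)
    nonneg = {"Ce_mg_L", "qe_mg_g", "t_min", "qt_mg_g", "T_K", "K_ads", "p_sigma"}
    for col in set(expected) & nonneg:
        bad = df.index[df[col] < 0].tolist()
        if bad:
            raise ValidationError(
                f"{path}: negative value in column {col!r} at data row(s) "
                f"{[i + 1 for i in bad]}"
            )
    return df


def read_table(path, schema: str, **meta):
    """Read a delimited file into the typed container for ``schema``.

    ``meta`` forwards container metadata that is not stored in the file
    (e.g. ``adsorbent_id`` and ``temperature`` for isotherms, usually
    carried in a YAML sidecar or CLI flags).
    """
    df = _read_frame(path, schema)
    try:
        if schema == "isotherm":
            return IsothermDataset(
                adsorbent_id=meta.get("adsorbent_id", "unknown"),
                temperature=meta.get("temperature", 293.0),
                ce=df["Ce_mg_L"].to_numpy(),
                qe=df["qe_mg_g"].to_numpy(),
            )
        if schema == "kinetics":
            return KineticTrace(t=df["t_min"].to_numpy(), qt=df["qt_mg_g"].to_numpy())
        if schema == "thermo":
            return ThermoSeries(
                temperatures=df["T_K"].to_numpy(),
                kads=df["K_ads"].to_numpy(),
                adsorbent_id=meta.get("adsorbent_id", "unknown"),
            )
        if schema == "titration":
            return TitrationCurve(
                ph_initial=df["pHi"].to_numpy(), delta_ph=df["delta_pH"].to_numpy()
            )
        if schema == "orbitals":
            return [
                OrbitalRecord(
                    species_id=str(r.species), e_homo=r.E_HOMO_eV, e_lumo=r.E_LUMO_eV
                )
                for r in df.itertuples()
            ]
        if schema == "sigma":
            return SigmaProfile(
                sigma=df["sigma_eA2"].to_numpy(), p_sigma=df["p_sigma"].to_numpy()
            )
        # bcp
        return [
            BcpRecord(bcp_id=str(r.bcp_id), rho=r.rho, lap_rho=r.lap_rho, g=r.G, v=r.V)
            for r in df.itertuples()
        ]
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_table(obj, path, delimiter: str = ",") -> None:
    """Write a typed container back to its delimited format.

    Inverse of :func:`read_table`: values are written with the shortest
    round-tripping float representation, so write-then-read is exact.
    """
    path = Path(path)
    if isinstance(obj, IsothermDataset):
        df = pd.DataFrame({"Ce_mg_L": obj.ce, "qe_mg_g": obj.qe})
    elif isinstance(obj, KineticTrace):
        df = pd.DataFrame({"t_min": obj.t, "qt_mg_g": obj.qt})
    elif isinstance(obj, ThermoSeries):
        df = pd.DataFrame({"T_K": obj.temperatures, "K_ads": obj.kads})
    elif isinstance(obj, TitrationCurve):
        df = pd.DataFrame({"pHi": obj.ph_initial, "delta_pH": obj.delta_ph})
    elif isinstance(obj, SigmaProfile):
        df = pd.DataFrame({"sigma_eA2": obj.sigma, "p_sigma": obj.p_sigma})
    elif isinstance(obj, list) and obj and isinstance(obj[0], OrbitalRecord):
        df = pd.DataFrame(
            {
                "species": [r.species_id for r in obj],
                "E_HOMO_eV": [r.e_homo for r in obj],
                "E_LUMO_eV": [r.e_lumo for r in obj],
            }
        )
    elif isinstance(obj, list) and obj and isinstance(obj[0], BcpRecord):
        df = pd.DataFrame(
            {
                "bcp_id": [r.bcp_id for r in obj],
                "rho": [r.rho for r in obj],
                "lap_rho": [r.lap_rho for r in obj],
                "G": [r.g for r in obj],
                "V": [r.v for r in obj],
            }
        )
    else:
        raise ValidationError(f"cannot serialize object of type {type(obj).__name__}")
    df.to_csv(path, sep=delimiter, index=False)
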
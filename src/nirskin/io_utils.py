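"""Configuration and table I/O: YAML skin models, CSV spectra and results.

CSV files carry a commented metadata header (``# key: value`` lines) so
every output records the seed and configuration hash that produced it;
``read_csv_with_meta`` round-trips these.  Skin-model YAML mirrors the
seven-layer table: one entry per layer with thickness, volume fractions,
anisotropy, refractive index and a power-law reduced-scattering reference.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .optical_properties import (
    ChromophoreSet,
    InvalidInputError,
    SkinLayer,
    SkinModel,
)

__all__ = [
    "SchemaError",
    "default_model_path",
    "load_skin_model",
    "load_chromophores_csv",
    "load_ad_csv",
    "write_csv_with_meta",
    "read_csv_with_meta",
    "config_hash",
]


class SchemaError(ValueError):
    """A config or table file violates its schema."""


def default_model_path() -> Path:
    """Path of the packaged seven-layer skin model file."""
    return Path(__file__).parent / "data" / "table1_skin.yaml"


def config_hash(obj: Any) -> str:
    """Short stable hash of a JSON-serialisable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def load_skin_model(
    path: str | Path, wavelengths: np.ndarray | None = None
) -> SkinModel:
    """Build a :class:`SkinModel` from a YAML layer file.

    ``wavelengths`` is the grid (nm) on which each layer's power-law μs′
    reference is tabulated; defaults to a 5 nm grid over 1000–1700 nm.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if wavelengths is None:
        wavelengths = np.arange(1000.0, 1701.0, 5.0)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if not isinstance(doc, dict) or "layers" not in doc:
        raise SchemaError(f"{path}: expected a mapping with a 'layers' list")
    layers = []
    for i, entry in enumerate(doc["layers"]):
        try:
            msp_ref = float(entry["mu_s_prime_ref_cm1"])
            msp_exp = float(entry.get("mu_s_prime_exponent", 1.0))
            layer = SkinLayer(
                name=str(entry["name"]),
                kind=str(entry["kind"]),
                thickness=float(entry["thickness_cm"]),
                C_B=float(entry["C_B"]),
                C_H2O=float(entry["C_H2O"]),
                mu_s_prime=msp_ref * (wavelengths / 1000.0) ** -msp_exp,
                g=float(entry.get("g", 0.9)),
                n=float(entry.get("n", 1.37)),
            )
        except KeyError as exc:
            raise SchemaError(f"{path}: layer {i}: missing field {exc}") from exc
        except InvalidInputError as exc:
            raise SchemaError(f"{path}: layer {i} ({entry.get('name')}): {exc}") from exc
        layers.append(layer)
    sup = doc.get("superstrate", {})
    return SkinModel(
        layers=tuple(layers),
        superstrate_n=float(sup.get("n", 1.4)),
        superstrate_thickness=float(sup.get("thickness_cm", 0.02)),
        ambient_n=float(doc.get("ambient_n", 1.0)),
    )


_CHROMOPHORE_COLUMNS = ("wavelength_nm", "mu_a_water", "mu_a_blood", "mu_a_other")


def load_chromophores_csv(path: str | Path) -> ChromophoreSet:
    """Chromophore spectra from CSV (wavelength_nm + three μa columns, cm⁻¹)."""
    df, _ = read_csv_with_meta(path)
    missing = [c for c in _CHROMOPHORE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise SchemaError(f"{path}: wavelength_nm must be strictly increasing")
    try:
        return ChromophoreSet(
            wavelengths=wl,
            mu_a_water=df["mu_a_water"].to_numpy(dtype=float),
            mu_a_blood=df["mu_a_blood"].to_numpy(dtype=float),
            mu_a_other=df["mu_a_other"].to_numpy(dtype=float),
        )
    except InvalidInputError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def load_ad_csv(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """A_D table (wavelength_nm, ad[, stderr]) plus its metadata header."""
    df, meta = read_csv_with_meta(path)
    for col in ("wavelength_nm", "ad"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    return df, meta


def write_csv_with_meta(
    path: str | Path, df: pd.DataFrame, meta: dict | None = None
) -> None:
    """Write a CSV with ``# key: value`` header lines before the table."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def read_csv_with_meta(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a CSV written by :func:`write_csv_with_meta`."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        try:
            df = pd.read_csv(fh)
        except Exception as exc:  # surface the offending file, not just pandas
            raise SchemaError(f"{path}: unparseable table: {exc}") from exc
    return df, meta
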
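"""Spectral CSV readers/writers, run configuration, display encoding.

Spectral files are plain CSV: either narrow (``wavelength_nm,value``) or
wide (first column ``wavelength_nm``, one column per item).  A database is
a directory of narrow files or a single wide file.  Reflectance validation
follows measurement practice: small under/overshoots (down to -0.05, up to
1.05) are clamped with a warning, anything beyond is rejected.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .spectra import ReflectanceSpectrum, SpectralGrid, Spectrum, resample

__all__ = [
    "read_spectral_csv",
    "read_spectral_database",
    "write_spectral_csv",
    "gamma_encode",
    "RunConfig",
    "SCHEMA_VERSION",
]

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


def _validate_columns(df: pd.DataFrame, path) -> None:
    if df.columns[0] != "wavelength_nm":
        raise ValueError(f"{path}: first column must be 'wavelength_nm'")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    if np.any(~np.isfinite(wl)):
        raise ValueError(f"{path}: non-finite wavelength")
    if np.any(np.diff(wl) <= 0):
        row = int(np.nonzero(np.diff(wl) <= 0)[0][0]) + 2  # 1-based + header
        raise ValueError(f"{path}: wavelengths not strictly increasing at row {row}")
    for col in df.columns[1:]:
        v = df[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(v)):
            row = int(np.nonzero(~np.isfinite(v))[0][0]) + 2
            raise ValueError(f"{path}: NaN or infinite value in '{col}' at row {row}")


def _make_spectrum(wl, v, kind: str, grid: SpectralGrid | None, name):
    src = SpectralGrid(wl[0], wl[-1], float(wl[1] - wl[0])) if _uniform(wl) else None
    if kind == "reflectance":
        if np.any(v < -0.05) or np.any(v > 1.05):
            raise ValueError(
                f"{name}: reflectance outside [-0.05, 1.05]; file rejected"
            )
        n_clamp = int(np.sum((v < 0) | (v > 1)))
        if n_clamp:
            warnings.warn(
                f"{name}: clamped {n_clamp} reflectance value(s) into [0, 1]"
            )
            log.warning("%s: clamped %d reflectance value(s)", name, n_clamp)
        v = np.clip(v, 0.0, 1.0)
        out_cls = ReflectanceSpectrum
    elif kind == "radiance":
        if np.any(v < 0):
            raise ValueError(f"{name}: negative radiant power; file rejected")
        out_cls = Spectrum
    else:
        raise ValueError("kind must be 'reflectance' or 'radiance'")
    if src is None:
        # non-uniform source sampling: interpolate directly onto the run grid
        if grid is None:
            raise ValueError(f"{name}: non-uniform sampling requires a target grid")
        vals = np.interp(grid.wavelengths, wl, v)
        return out_cls(grid, np.clip(vals, 0, 1) if kind == "reflectance" else vals)
    s = out_cls(src, v)
    return resample(s, grid) if grid is not None else s


def _uniform(wl: np.ndarray) -> bool:
    d = np.diff(wl)
    return bool(np.allclose(d, d[0], rtol=0, atol=1e-9))


def read_spectral_csv(path, kind: str = "reflectance", grid: SpectralGrid | None = None):
    """Read a narrow spectral CSV; validates, clamps, resamples to ``grid``.

    Returns a single spectrum for a narrow file, or a dict of name ->
    spectrum for a wide file.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _validate_columns(df, path)
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    if len(df.columns) == 2:
        v = df[df.columns[1]].to_numpy(dtype=float)
        return _make_spectrum(wl, v, kind, grid, path.name)
    return {
        col: _make_spectrum(
            wl, df[col].to_numpy(dtype=float), kind, grid, f"{path.name}:{col}"
        )
        for col in df.columns[1:]
    }


def read_spectral_database(
    path, kind: str = "reflectance", grid: SpectralGrid | None = None
) -> list:
    """Read a database: a directory of narrow CSVs or one wide CSV."""
    path = Path(path)
    if path.is_dir():
        items = []
        for f in sorted(path.glob("*.csv")):
            got = read_spectral_csv(f, kind, grid)
            items.extend(got.values() if isinstance(got, dict) else [got])
        if not items:
            raise ValueError(f"{path}: no CSV files found")
        return items
    got = read_spectral_csv(path, kind, grid)
    return list(got.values()) if isinstance(got, dict) else [got]


def write_spectral_csv(path, spectrum_or_list) -> None:
    """Write one spectrum (narrow) or several (wide) as CSV."""
    path = Path(path)
    items = (
        spectrum_or_list
        if isinstance(spectrum_or_list, (list, tuple))
        else [spectrum_or_list]
    )
    grid = items[0].grid
    data = {"wavelength_nm": grid.wavelengths}
    if len(items) == 1:
        data["value"] = items[0].values
    else:
        for i, s in enumerate(items):
            data[f"item_{i:04d}"] = s.values
    pd.DataFrame(data).to_csv(path, index=False)


def gamma_encode(c, gamma: float = 2.2) -> np.ndarray:
    """Display (gamma) encoding of rgb coordinates: clip to [0,1], power 1/gamma."""
    v = np.clip(np.asarray(c, dtype=float), 0.0, 1.0)
    return v ** (1.0 / gamma)


_CONFIG_KEYS = {
    "grid",
    "seed",
    "daylight_model",
    "reflectance_model",
    "tolerances",
    "out",
    "log_level",
}


@dataclass
class RunConfig:
    """Validated run configuration (JSON or YAML); unknown keys rejected."""

    grid: SpectralGrid = field(default_factory=SpectralGrid)
    seed: int = 0
    daylight_model: dict = field(default_factory=dict)
    reflectance_model: dict = field(default_factory=dict)
    tolerances: dict = field(default_factory=dict)
    out: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = (
                json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
            ) or {}
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "grid" in raw:
            g = raw["grid"]
            raw["grid"] = SpectralGrid(
                float(g["lambda_uv"]), float(g["lambda_ir"]), float(g.get("step", 1.0))
            )
        if "seed" in raw and not isinstance(raw["seed"], int):
            raise ValueError("seed must be an explicit integer")
        return cls(**raw)
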
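"""Bundled colorimetric constants and deterministic demo data.

Ships the CIE 1931 2-degree color-matching functions and the CIE d65
average-daylight spectrum (standard published 5 nm tables, linearly
interpolated onto the working grid), a synthetic poppy-like demo
reflectance, and small synthetic spectral "databases" generated on the fly
from fixed seeds with the default generative models.  The standard rgb
crate basis for d65 is computed once per grid and cached.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from .spectra import Cmfs, ReflectanceSpectrum, SpectralGrid, Spectrum

__all__ = [
    "default_grid",
    "d65",
    "cie1931_cmfs",
    "poppy_like_reflectance",
    "standard_basis",
    "standard_rgb_cmfs",
    "synthetic_vegetation_database",
    "synthetic_daylight_database",
]


def default_grid() -> SpectralGrid:
    """The default working grid: 380-720 nm at 1 nm."""
    return SpectralGrid(380.0, 720.0, 1.0)


def _read_table(name: str) -> pd.DataFrame:
    with resources.files("colorgrain.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


@lru_cache(maxsize=None)
def d65(grid: SpectralGrid | None = None) -> Spectrum:
    """CIE d65 average daylight, resampled onto the grid."""
    grid = grid or default_grid()
    tab = _read_table("d65_5nm.csv")
    v = np.interp(grid.wavelengths, tab["wavelength_nm"], tab["value"])
    return Spectrum(grid, v)


@lru_cache(maxsize=None)
def cie1931_cmfs(grid: SpectralGrid | None = None) -> Cmfs:
    """CIE 1931 2-degree observer xyz CMFs, resampled onto the grid."""
    grid = grid or default_grid()
    tab = _read_table("cie1931_2deg_5nm.csv")
    v = np.column_stack(
        [np.interp(grid.wavelengths, tab["wavelength_nm"], tab[c]) for c in "xyz"]
    )
    return Cmfs(grid, v, basis="xyz")


@lru_cache(maxsize=None)
def poppy_like_reflectance(grid: SpectralGrid | None = None) -> ReflectanceSpectrum:
    """A synthetic poppy-like flower reflectance (demo fixture, not measured).

    Low and flat through the blue and green, rising steeply past ~600 nm:
    the signature shape of a vivid red flower petal.
    """
    grid = grid or default_grid()
    wl = grid.wavelengths
    v = 0.04 + 0.45 / (1.0 + np.exp(-(wl - 605.0) / 18.0))
    return ReflectanceSpectrum(grid, np.clip(v, 0.0, 1.0))


@lru_cache(maxsize=None)
def standard_basis(grid: SpectralGrid | None = None):
    """The canonical (crate) basis of d65 on the grid.

    Returns ``(tripartition, basis)``; computed by exhaustive search plus
    refinement, then cached per grid.
    """
    from .solid import canonical_basis, find_largest_crate

    grid = grid or default_grid()
    D = d65(grid)
    cmfs = cie1931_cmfs(grid)
    t = find_largest_crate(D, cmfs)
    return t, canonical_basis(D, t, cmfs)


@lru_cache(maxsize=None)
def standard_rgb_cmfs(grid: SpectralGrid | None = None) -> Cmfs:
    """CMFs in the rgb-parts basis of the standard d65 crate."""
    from .solid import rgb_cmfs

    grid = grid or default_grid()
    _, basis = standard_basis(grid)
    return rgb_cmfs(basis, cie1931_cmfs(grid))


def synthetic_vegetation_database(
    grid: SpectralGrid | None = None, n: int = 219, seed: int = 219
) -> list[ReflectanceSpectrum]:
    """A vegetation-like synthetic reflectance database (219 items by default).

    Generated from the default natural-statistics reflectance model with a
    fixed seed; the item count mirrors typical published vegetation
    databases.  Synthetic stand-in: not measured data.
    """
    from .generate import ReflectanceModel, generate_reflectance

    grid = grid or default_grid()
    model = ReflectanceModel.default(grid)
    return generate_reflectance(model, n, seed=seed)


def synthetic_daylight_database(
    grid: SpectralGrid | None = None, n: int = 52, seed: int = 52
) -> list[Spectrum]:
    """A daylight-like synthetic radiant database (52 items by default).

    Generated from the default daylight model with a fixed seed; the item
    count mirrors the size of typical daylight databases.  Synthetic
    stand-in: not measured data.
    """
    from .generate import DaylightModel, generate_daylight

    grid = grid or default_grid()
    model = DaylightModel.default(grid)
    return generate_daylight(model, n, seed=seed)
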
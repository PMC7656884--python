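"""Wavelength grids, spectra, color-matching functions and tristimulus algebra.

Colorimetry is the study of the linear operator that maps radiant power
spectra to 3-vectors ("colors").  This module provides the sampled
representations of that machinery: uniform wavelength grids over the visual
range, radiant and reflectance spectra on such grids, color-matching
functions (CMFs) in either the CIE xyz basis or the "rgb-parts" basis
derived from a tripartition of the standard illuminant, trapezoid-rule
tristimulus integration, white-anchored object-color coordinates (a
von-Kries-style color constancy), and the Maxwell chromaticity projection.

All quadrature in the package goes through :func:`cell_weights` /
:func:`tristimulus` so that partial-range integrals elsewhere (the color
solid, the crate search, canonical spectra) are mutually consistent to
machine precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, NamedTuple

import numpy as np

__all__ = [
    "SpectralGrid",
    "Spectrum",
    "ReflectanceSpectrum",
    "Cmfs",
    "Tristimulus",
    "ObjectColor",
    "resample",
    "cell_weights",
    "tristimulus",
    "object_color",
    "maxwell_chromaticity",
    "is_metameric",
]

#: Approximate limits of the visual range, in nm.
LAMBDA_UV = 380.0
LAMBDA_IR = 720.0


@dataclass(frozen=True)
class SpectralGrid:
    """A uniformly sampled wavelength interval, inclusive of both endpoints.

    Parameters
    ----------
    lambda_uv, lambda_ir:
        Lower and upper limits of the visual range in nm.
    step:
        Sampling interval in nm.
    """

    lambda_uv: float = LAMBDA_UV
    lambda_ir: float = LAMBDA_IR
    step: float = 1.0
    wavelengths: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not (self.step > 0):
            raise ValueError("step must be positive")
        if not (self.lambda_uv < self.lambda_ir):
            raise ValueError("lambda_uv must be below lambda_ir")
        n = int(round((self.lambda_ir - self.lambda_uv) / self.step)) + 1
        wl = self.lambda_uv + self.step * np.arange(n)
        if abs(wl[-1] - self.lambda_ir) > 1e-9:
            raise ValueError("grid limits are not an integer number of steps apart")
        wl.setflags(write=False)
        object.__setattr__(self, "wavelengths", wl)

    def __len__(self) -> int:
        return len(self.wavelengths)

    @property
    def width(self) -> float:
        """Width of the visual range in nm."""
        return self.lambda_ir - self.lambda_uv

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralGrid):
            return NotImplemented
        return (
            self.lambda_uv == other.lambda_uv
            and self.lambda_ir == other.lambda_ir
            and self.step == other.step
        )

    def __hash__(self) -> int:
        return hash((self.lambda_uv, self.lambda_ir, self.step))


def _as_values(values, grid: SpectralGrid) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.shape != (len(grid),):
        raise ValueError(
            f"values shape {v.shape} does not match grid length {len(grid)}"
        )
    if not np.all(np.isfinite(v)):
        raise ValueError("spectral values must be finite")
    return v


@dataclass(frozen=True)
class Spectrum:
    """A sampled radiant power density spectrum (arbitrary units, >= 0)."""

    grid: SpectralGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        v = _as_values(self.values, self.grid)
        if np.any(v < 0):
            raise ValueError("radiant power must be nonnegative")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    def __mul__(self, other):
        if isinstance(other, (ReflectanceSpectrum, Spectrum)):
            if other.grid != self.grid:
                raise ValueError("grids differ; resample first")
            return Spectrum(self.grid, self.values * other.values)
        return Spectrum(self.grid, self.values * float(other))

    __rmul__ = __mul__


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """A sampled spectral reflectance factor, dimensionless in [0, 1]."""

    grid: SpectralGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        v = _as_values(self.values, self.grid)
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("reflectance must lie in [0, 1]")
        v = np.clip(v, 0.0, 1.0)
        v.setflags(write=False)
        object.__setattr__(self, "values", v)


Basis = Literal["xyz", "rgb-parts"]


@dataclass(frozen=True)
class Cmfs:
    """Three color-matching functions sampled on a common grid.

    ``values`` has shape (n, 3).  The basis label records whether the
    functions are the CIE 1931 xyz observer or the rgb-parts functions
    obtained by re-expressing the observer in the crate basis of a
    standard illuminant.
    """

    grid: SpectralGrid
    values: np.ndarray
    basis: Basis = "xyz"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.grid), 3):
            raise ValueError("cmfs must have shape (len(grid), 3)")
        if not np.all(np.isfinite(v)):
            raise ValueError("cmfs must be finite")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class Tristimulus:
    """A color: the 3-vector image of a radiant spectrum, in a stated basis."""

    c: np.ndarray
    basis: str = "xyz"

    def __post_init__(self) -> None:
        v = np.asarray(self.c, dtype=float)
        if v.shape != (3,) or not np.all(np.isfinite(v)):
            raise ValueError("tristimulus must be a finite 3-vector")
        v.setflags(write=False)
        object.__setattr__(self, "c", v)


class ObjectColor(NamedTuple):
    """White-anchored object-color coordinates {r, g, b}.

    For ecologically generated inputs these typically lie in the unit cube;
    values slightly outside are possible (negative CMF lobes) and only
    warned about, not rejected.
    """

    r: float
    g: float
    b: float

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=float)


# ---------------------------------------------------------------------------
# operations


def resample(spectrum, grid: SpectralGrid):
    """Resample a spectrum onto ``grid`` by linear interpolation.

    Inside the source support the values are linearly interpolated; outside
    it they are extended as constants.  Reflectance outputs are clipped to
    [0, 1].  Raises ``ValueError`` when the grids do not overlap.
    """
    src = spectrum.grid
    if src == grid:
        return spectrum
    if src.lambda_ir < grid.lambda_uv or src.lambda_uv > grid.lambda_ir:
        raise ValueError("source and target grids do not overlap")
    v = np.interp(grid.wavelengths, src.wavelengths, spectrum.values)
    if isinstance(spectrum, ReflectanceSpectrum):
        return ReflectanceSpectrum(grid, np.clip(v, 0.0, 1.0))
    return Spectrum(grid, v)


def cell_weights(grid: SpectralGrid) -> np.ndarray:
    """Trapezoid-rule quadrature weights (interior ``step``, ends ``step/2``).

    Equivalently: the width of the sample cell
    ``[lambda_i - step/2, lambda_i + step/2]`` clipped to the grid limits.
    """
    w = np.full(len(grid), grid.step)
    w[0] = w[-1] = grid.step / 2.0
    return w


def tristimulus(s: Spectrum, cmfs: Cmfs) -> Tristimulus:
    """Integrate a radiant spectrum against the CMFs (trapezoid rule).

    The spectrum is resampled onto the CMF grid when needed.  The map is
    linear in ``s``; negative spectral values are rejected.
    """
    if not isinstance(s, Spectrum):
        raise TypeError("tristimulus expects a radiant Spectrum")
    s = resample(s, cmfs.grid)
    w = cell_weights(cmfs.grid)
    c = (s.values * w) @ cmfs.values
    return Tristimulus(c, basis=cmfs.basis)


def object_color(
    F: ReflectanceSpectrum, illuminant: Spectrum, cmfs: Cmfs
) -> ObjectColor:
    """White-anchored color of a reflectance under an illuminant.

    The coordinates are the componentwise ratio of the tristimulus of the
    reflected beam ``F * D`` to that of the white reference beam ``D``.
    Anchoring makes the result invariant under rescaling of the illuminant
    and implements the automatic white balance of object-color vision.
    The CMFs should be in the rgb-parts basis for the coordinates to be
    the {r, g, b} of the unit cube.
    """
    F = resample(F, cmfs.grid)
    D = resample(illuminant, cmfs.grid)
    white = tristimulus(D, cmfs).c
    if np.any(np.abs(white) < 1e-12 * max(np.abs(white).max(), 1e-300)) or np.all(
        white == 0
    ):
        raise ValueError("degenerate illuminant: zero white tristimulus component")
    beam = tristimulus(Spectrum(cmfs.grid, F.values * D.values), cmfs).c
    c = beam / white
    if np.any(c < -0.05) or np.any(c > 1.05):
        warnings.warn(
            "object color far outside the unit cube; input may not be "
            "ecologically plausible",
            stacklevel=2,
        )
    return ObjectColor(*c)


def maxwell_chromaticity(t: Tristimulus | np.ndarray) -> np.ndarray:
    """Project a color from the black point onto the unit-sum triangle.

    Returns the first two barycentric coordinates ``t / sum(t)``; the third
    is their complement to 1.
    """
    c = t.c if isinstance(t, Tristimulus) else np.asarray(t, dtype=float)
    s = c.sum()
    if s == 0:
        raise ValueError("cannot project the black point (zero component sum)")
    return (c / s)[:2]


def is_metameric(
    s1: Spectrum,
    s2: Spectrum,
    cmfs: Cmfs,
    tol: float = 1e-8,
    white: Tristimulus | None = None,
) -> bool:
    """Whether two radiant spectra map to the same color.

    The tristimulus difference norm is compared to ``tol`` relative to the
    norm of the white reference (by default the larger of the two spectra's
    own tristimulus norms).
    """
    t1 = tristimulus(s1, cmfs).c
    t2 = tristimulus(s2, cmfs).c
    ref = np.linalg.norm(white.c) if white is not None else max(
        np.linalg.norm(t1), np.linalg.norm(t2), 1e-300
    )
    return bool(np.linalg.norm(t1 - t2) <= tol * ref)
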
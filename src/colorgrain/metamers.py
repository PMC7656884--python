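"""Ecologically valid metameric blacks and metamer sets.

A metameric black is a reflectance perturbation whose reflected beam under
the standard illuminant has zero tristimulus: adding it to a spectrum
changes nothing visible under that illuminant.  Blacks are built from four
random natural-statistics reflectance instances, apodized with a Hanning
window (raw combinations have unusably large amplitudes near the spectrum
limits), and combined through the one-dimensional null space of their 3x4
tristimulus matrix.  A metamer of a color is then its canonical three-level
spectrum plus a scaled black, the scale bounded by the (0, 1) physical
range -- colors on the boundary of the solid have no headroom and hence no
metamers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .generate import ReflectanceModel, sample_signatures
from .kubelka_munk import g_reflectance
from .solid import CanonicalBasis, canonical_spectrum
from .spectra import (
    Cmfs,
    ObjectColor,
    ReflectanceSpectrum,
    SpectralGrid,
    Spectrum,
    cell_weights,
    resample,
)

__all__ = ["MetamericBlack", "random_black", "max_scale", "metamer_set"]


@dataclass(frozen=True)
class MetamericBlack:
    """A reflectance perturbation with zero color under the standard beam."""

    grid: SpectralGrid
    delta: np.ndarray
    tristimulus_norm: float  # residual color magnitude relative to white

    def __post_init__(self) -> None:
        v = np.asarray(self.delta, dtype=float)
        if v.shape != (len(self.grid),):
            raise ValueError("delta length must match grid")
        v.setflags(write=False)
        object.__setattr__(self, "delta", v)


def _tri_matrix(illuminant: Spectrum, cmfs: Cmfs) -> np.ndarray:
    """Rows of w * D * cmf: maps a reflectance value vector to tristimulus."""
    D = resample(illuminant, cmfs.grid)
    return (D.values * cell_weights(cmfs.grid))[:, None] * cmfs.values


def random_black(
    generator: ReflectanceModel,
    illuminant: Spectrum,
    cmfs: Cmfs,
    seed=None,
    max_tries: int = 10,
) -> MetamericBlack:
    """Draw an ecologically valid metameric black (unit rms).

    Four random reflectance instances are Hanning-windowed; the unique (up
    to scale) null vector of their 3x4 tristimulus matrix gives a linear
    combination with zero color under ``illuminant``.  The sign is fixed by
    making the largest-magnitude coefficient positive.  Rank-deficient
    draws are retried up to ``max_tries`` times.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    grid = cmfs.grid
    A = _tri_matrix(illuminant, cmfs)
    window = np.hanning(len(grid))
    white_norm = np.linalg.norm(A.sum(axis=0))
    for _ in range(max_tries):
        F = g_reflectance(sample_signatures(generator, 4, rng))  # (4, n)
        W = F * window  # apodized instances
        T = W @ A  # (4, 3)
        u, s, vt = np.linalg.svd(T.T)  # null space of the 3x4 map
        if s[-1] > 1e-6 * s[0]:
            coeff = vt[-1]
            if coeff[np.argmax(np.abs(coeff))] < 0:
                coeff = -coeff
            delta = coeff @ W
            rms = np.sqrt(np.mean(delta**2))
            if rms > 1e-12:
                delta = delta / rms
                resid = np.linalg.norm(delta @ A) / white_norm
                return MetamericBlack(grid, delta, resid)
    raise ValueError("degenerate draws: could not build a metameric black")


def max_scale(black: MetamericBlack, base: ReflectanceSpectrum) -> float:
    """Largest s >= 0 keeping base + s * delta inside [0, 1] everywhere.

    Closed form from per-sample headroom; the scaled sum touches 0 or 1 at
    some sample.  Boundary colors (base touching 0 or 1 where the black is
    active) give s = 0: they have no metamers.
    """
    d = black.delta
    if np.all(d == 0):
        raise ValueError("metameric black is identically zero")
    b = base.values
    with np.errstate(divide="ignore"):
        up = np.where(d > 0, (1.0 - b) / np.where(d > 0, d, 1.0), np.inf)
        dn = np.where(d < 0, b / np.where(d < 0, -d, 1.0), np.inf)
    return float(max(min(up.min(), dn.min()), 0.0))


def metamer_set(
    c: ObjectColor,
    n: int,
    generator: ReflectanceModel,
    basis: CanonicalBasis,
    cmfs: Cmfs,
    seed=None,
    scaling: str = "max",
) -> list[ReflectanceSpectrum]:
    """Random metamers of a color: canonical spectrum + scaled random blacks.

    Every instance stays inside [0, 1] and maps to the same object color
    under the standard illuminant.  ``scaling='max'`` uses the full physical
    headroom (a deliberately pessimistic choice); ``'uniform'`` draws the
    scale uniformly in [0, s_max].
    """
    if scaling not in ("max", "uniform"):
        raise ValueError("scaling must be 'max' or 'uniform'")
    rgb = np.asarray(c, dtype=float)
    if np.any(rgb <= 0.0) or np.any(rgb >= 1.0):
        raise ValueError("color must lie strictly inside the unit cube")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    base = canonical_spectrum(c, basis)
    out = []
    for _ in range(n):
        black = random_black(generator, basis.illuminant, cmfs, rng)
        s = max_scale(black, base)
        if scaling == "uniform":
            s = float(rng.uniform(0.0, s))
        v = np.clip(base.values + s * black.delta, 0.0, 1.0)
        out.append(ReflectanceSpectrum(base.grid, v))
    return out
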
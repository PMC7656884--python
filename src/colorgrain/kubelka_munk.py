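"""Homomorphic transforms between the ecological and the physical domain.

Reflectance factors live in the open unit interval and radiant power on the
positive half-line; linear statistics (means, PCA, Fourier synthesis) applied
there can and do produce nonsensical values.  The cure is homomorphic
filtering: map to a domain where the constraint set is the full real line,
operate linearly there, and map back.  For reflectances the physical domain
is the log *spectral signature* ``rho = log(K/S)``, the log of the
Kubelka-Munk absorption-to-scattering cross-section ratio of an optically
thick turbid layer,

    K/S = (1 - R)^2 / (2 R),

a quantity that is a true object property.  For radiant power the physical
domain is simply the logarithm.  Statistics computed in the physical domain
and mapped back can never leave the physical range.

``f_signature`` and ``g_reflectance`` are the mutually inverse bijections
f: (0,1) -> R and g: R -> (0,1); both are strictly decreasing (more
absorption, less reflectance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .spectra import ReflectanceSpectrum, SpectralGrid, Spectrum

__all__ = [
    "SignatureSpectrum",
    "f_signature",
    "g_reflectance",
    "reflectance_to_physical",
    "physical_to_reflectance",
    "radiance_to_physical",
    "physical_to_radiance",
    "clamp_count",
]

log = logging.getLogger(__name__)

#: Reflectances at exactly 0 or 1 are clamped inward by this amount.
CLAMP_EPS = 1e-4

# running count of clamped samples, for diagnostics
_clamp_count = 0


def clamp_count() -> int:
    """Number of boundary samples clamped so far in this process."""
    return _clamp_count


@dataclass(frozen=True)
class SignatureSpectrum:
    """Log spectral signature log(K/S) per wavelength (full real line)."""

    grid: SpectralGrid
    rho: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.rho, dtype=float)
        if v.shape != (len(self.grid),):
            raise ValueError("rho length must match grid")
        if not np.all(np.isfinite(v)):
            raise ValueError("signature must be finite at every sample")
        v.setflags(write=False)
        object.__setattr__(self, "rho", v)


def f_signature(r, clamp: bool = False):
    """Map reflectance in (0, 1) to the log signature rho = log((1-r)^2/(2r)).

    Strictly decreasing, with f -> +inf as r -> 0 and -inf as r -> 1.
    Exact 0 or 1 raise unless ``clamp=True``, which nudges them inward by
    ``CLAMP_EPS`` (counted, logged).
    """
    global _clamp_count
    r = np.asarray(r, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    bad = (r <= 0.0) | (r >= 1.0)
    if np.any(bad):
        if not clamp:
            raise ValueError("reflectance must lie strictly inside (0, 1)")
        n = int(bad.sum())
        _clamp_count += n
        log.info("clamped %d boundary reflectance sample(s) by %g", n, CLAMP_EPS)
        r = np.clip(r, CLAMP_EPS, 1.0 - CLAMP_EPS)
    rho = 2.0 * np.log1p(-r) - np.log(2.0 * r)
    return float(rho[0]) if scalar else rho


def g_reflectance(rho):
    """Inverse of :func:`f_signature`; total on the reals, image (0, 1).

    With k = exp(rho), the Kubelka-Munk relation gives the quadratic
    r^2 - 2 r (1 + k) + 1 = 0 whose root in (0, 1) is written in the
    cancellation-free form r = 1 / (1 + k + sqrt(k (k + 2))).
    """
    rho = np.asarray(rho, dtype=float)
    scalar = rho.ndim == 0
    k = np.exp(np.atleast_1d(rho))
    r = 1.0 / (1.0 + k + np.sqrt(k * (k + 2.0)))
    return float(r[0]) if scalar else r


def reflectance_to_physical(F: ReflectanceSpectrum) -> SignatureSpectrum:
    """Pointwise map of a reflectance spectrum to the signature domain."""
    return SignatureSpectrum(F.grid, f_signature(F.values, clamp=True))


def physical_to_reflectance(sig: SignatureSpectrum) -> ReflectanceSpectrum:
    """Pointwise inverse map; output is strictly inside (0, 1)."""
    return ReflectanceSpectrum(sig.grid, g_reflectance(sig.rho))


def radiance_to_physical(s: Spectrum, eps: float = 1e-12) -> SignatureSpectrum:
    """Natural log of radiant power (values clamped below at ``eps``, logged).

    Multiplication of beams becomes addition, normalization becomes
    subtraction of a constant.
    """
    global _clamp_count
    v = s.values
    n = int(np.sum(v < eps))
    if n:
        _clamp_count += n
        log.info("clamped %d nonpositive radiance sample(s) at %g", n, eps)
        v = np.maximum(v, eps)
    return SignatureSpectrum(s.grid, np.log(v))


def physical_to_radiance(sig: SignatureSpectrum) -> Spectrum:
    """Exponential inverse of :func:`radiance_to_physical`."""
    return Spectrum(sig.grid, np.exp(sig.rho))
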
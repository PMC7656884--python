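"""Generative statistical models of daylight and object reflectance spectra.

Real spectral databases are far too small to sample metamers or illuminant
variation densely, so the ecology is summarized by generative models and
novel instances are drawn from those.  Both models operate in the physical
domain (log radiant power for daylights, log spectral signature for
reflectances) so that every generated instance is automatically physical:
daylights strictly positive, reflectances strictly inside (0, 1).

Daylight model: ensemble mean + a few low-order principal components
(dominantly spectral slope, then curvature) with multinormal coefficients,
plus a weak "fractal fuzz" residual.  Reflectance model: a baseline
signature (database mean or a constant spectral slope) plus a fractal
articulation whose Fourier power falls off as frequency to the inverse
fourth power and whose autocorrelation halfwidth is about the width of the
visual range -- natural spectra are only gradually articulated.

The fractal articulation is synthesized with random phases on an extended
periodic support; the support length is solved from the requested
correlation halfwidth, and the visual-range window is then cropped out.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from .kubelka_munk import f_signature, g_reflectance
from .spectra import (
    Cmfs,
    ReflectanceSpectrum,
    SpectralGrid,
    Spectrum,
)

__all__ = [
    "DaylightModel",
    "ReflectanceModel",
    "SpectralHistogram",
    "ArticulationSpectrum",
    "fractal_articulation",
    "bump_articulation",
    "generate_daylight",
    "generate_reflectance",
    "sample_signatures",
    "spectral_histogram",
    "articulation_power_spectrum",
    "autocorrelation_halfwidth",
    "fit_daylight_model",
    "fit_reflectance_model",
]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# model parameter sets


@dataclass(frozen=True)
class DaylightModel:
    """Generative model of daylight radiant spectra (log domain).

    ``pc_basis`` rows are unit-rms principal directions; ``pc_cov`` is the
    covariance of their coefficients (log units squared).  The residual
    articulation ("fractal fuzz") has power-law exponent ``fuzz_exponent``
    and rms ``fuzz_amplitude`` in log units.
    """

    grid: SpectralGrid
    mean_log: np.ndarray
    pc_basis: np.ndarray  # (k, n), k <= 3
    pc_cov: np.ndarray  # (k, k)
    fuzz_exponent: float = 4.0
    fuzz_amplitude: float = 0.01

    def __post_init__(self) -> None:
        k = self.pc_basis.shape[0] if self.pc_basis.size else 0
        if k > 3:
            raise ValueError("at most 3 principal components")
        cov = np.atleast_2d(np.asarray(self.pc_cov, dtype=float))
        if cov.shape != (k, k) or not np.allclose(cov, cov.T):
            raise ValueError("pc_cov must be symmetric (k, k)")
        if k and np.linalg.eigvalsh(cov).min() < -1e-12:
            raise ValueError("pc_cov must be positive semidefinite")
        if self.fuzz_amplitude < 0:
            raise ValueError("fuzz_amplitude must be >= 0")

    @classmethod
    def default(cls, grid: SpectralGrid | None = None) -> "DaylightModel":
        """Mean = log d65; PCs = Legendre slope and curvature (unit rms)
        with coefficient SDs 0.15 and 0.05 log units; fuzz 0.01 at exponent 4."""
        from .fixtures import d65, default_grid

        grid = grid or default_grid()
        D = d65(grid)
        mean_log = np.log(D.values / D.values.mean())
        x = (
            2.0
            * (grid.wavelengths - grid.lambda_uv)
            / (grid.lambda_ir - grid.lambda_uv)
            - 1.0
        )
        p1 = x
        p2 = 0.5 * (3.0 * x**2 - 1.0)
        basis = np.vstack(
            [p1 / np.sqrt(np.mean(p1**2)), p2 / np.sqrt(np.mean(p2**2))]
        )
        cov = np.diag([0.15**2, 0.05**2])
        return cls(grid, mean_log, basis, cov)


@dataclass(frozen=True)
class ReflectanceModel:
    """Generative model of object reflectance spectra (signature domain).

    The baseline is either an explicit mean signature spectrum or a constant
    spectral slope (per nm, about a mid-gray level); the articulation is a
    fractal with power-law exponent ``articulation_exponent`` (default 4,
    i.e. fractal dimension two), rms ``articulation_amplitude`` in signature
    units and autocorrelation halfwidth ``correlation_halfwidth`` nm.
    """

    grid: SpectralGrid
    baseline_signature: np.ndarray | None = None
    baseline_slope: float = -0.004
    articulation_amplitude: float = 1.0
    articulation_exponent: float = 4.0
    correlation_halfwidth: float | None = None  # default: visual-range width
    flavor: str = "fourier"  # or "bumps"

    def __post_init__(self) -> None:
        if self.articulation_amplitude < 0:
            raise ValueError("articulation amplitude must be >= 0")
        if self.articulation_exponent <= 1:
            raise ValueError("articulation exponent must exceed 1")
        if self.flavor not in ("fourier", "bumps"):
            raise ValueError("flavor must be 'fourier' or 'bumps'")

    @property
    def halfwidth(self) -> float:
        return (
            self.correlation_halfwidth
            if self.correlation_halfwidth is not None
            else self.grid.width
        )

    def baseline(self) -> np.ndarray:
        if self.baseline_signature is not None:
            return np.asarray(self.baseline_signature, dtype=float)
        wl = self.grid.wavelengths
        mid = 0.5 * (self.grid.lambda_uv + self.grid.lambda_ir)
        return self.baseline_slope * (wl - mid)

    @classmethod
    def default(cls, grid: SpectralGrid | None = None) -> "ReflectanceModel":
        from .fixtures import default_grid

        return cls(grid or default_grid())


@dataclass(frozen=True)
class SpectralHistogram:
    """Per-wavelength median and quartiles of a signature-domain ensemble."""

    grid: SpectralGrid
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        if not (
            np.all(self.lower <= self.median + 1e-12)
            and np.all(self.median <= self.upper + 1e-12)
        ):
            raise ValueError("quartiles must be ordered at every wavelength")


@dataclass(frozen=True)
class ArticulationSpectrum:
    """Ensemble-mean articulation power spectrum and its log-log slope."""

    frequencies: np.ndarray  # cycles per visual range, > 0
    power: np.ndarray
    slope: float
    fit_band: tuple[float, float] = (4.0, 40.0)


# ---------------------------------------------------------------------------
# fractal synthesis


@lru_cache(maxsize=32)
def _half_crossing(exponent: float, n_terms: int = 400) -> float:
    """Angle u where the harmonic-sum autocorrelation of a k^-exponent
    power spectrum first drops to half its peak."""
    k = np.arange(1, n_terms + 1)
    p = k ** (-float(exponent))
    total = p.sum()

    def h(u):
        return np.sum(p * np.cos(k * u)) - 0.5 * total

    return float(brentq(h, 1e-6, np.pi))


def fractal_articulation(
    grid: SpectralGrid,
    exponent: float,
    amplitude: float,
    seed=None,
    halfwidth: float | None = None,
    n: int = 1,
) -> np.ndarray:
    """Zero-mean fractal articulations with a power-law Fourier spectrum.

    Random-phase synthesis with amplitude spectrum proportional to
    ``frequency ** (-exponent / 2)`` on an extended periodic support (no DC
    term), rescaled so the process rms equals ``amplitude``, then cropped to
    the grid window.  The support length is solved from ``halfwidth`` (nm;
    default: the visual-range width) so the autocorrelation of the process
    drops to one half at that lag.  Returns shape ``(n, len(grid))``.
    """
    rng = _rng(seed)
    m = len(grid)
    if amplitude == 0:
        return np.zeros((n, m))
    hw = grid.width if halfwidth is None else float(halfwidth)
    L_ext = 2.0 * np.pi * hw / _half_crossing(float(exponent))
    n_ext = max(int(np.ceil(L_ext / grid.step)), m + 1)
    n_ext += n_ext % 2
    k = np.arange(1, n_ext // 2 + 1)
    amp = k ** (-exponent / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n, len(k)))
    spec = np.zeros((n, n_ext // 2 + 1), dtype=complex)
    spec[:, 1:] = amp * np.exp(1j * phases)
    x = np.fft.irfft(spec, n=n_ext, axis=1)
    rms = np.sqrt(np.mean(x[0] ** 2))  # deterministic: amplitudes are fixed
    return x[:, :m] * (amplitude / rms)


def bump_articulation(
    grid: SpectralGrid,
    amplitude: float,
    seed=None,
    halfwidth: float | None = None,
    n: int = 1,
    density: float = 0.2,
) -> np.ndarray:
    """Alternative articulation flavor: random Gaussian bumps.

    Many independent physical causes each imprint a local structure of a
    single spectral width at a uniformly random location.  ``density`` is
    the expected number of bumps per bump width.  Each instance is rescaled
    to rms ``amplitude`` over its extended support.
    """
    rng = _rng(seed)
    m = len(grid)
    if amplitude == 0:
        return np.zeros((n, m))
    hw = grid.width if halfwidth is None else float(halfwidth)
    sigma = hw / (2.0 * np.sqrt(np.log(2.0)))  # Gaussian autocorr halfwidth = hw
    lo = grid.lambda_uv - 3.0 * sigma
    hi = grid.lambda_ir + 3.0 * sigma
    n_bumps = max(8, int(np.ceil(density * (hi - lo) / sigma)))
    wl = grid.wavelengths
    out = np.empty((n, m))
    for i in range(n):
        centers = rng.uniform(lo, hi, n_bumps)
        amps = rng.standard_normal(n_bumps)
        x = (amps[:, None] * np.exp(-((wl - centers[:, None]) ** 2) / (2 * sigma**2))).sum(
            axis=0
        )
        x -= x.mean()
        rms = np.sqrt(np.mean(x**2))
        out[i] = x * (amplitude / rms) if rms > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# instance generation


def sample_signatures(model: ReflectanceModel, n: int, seed=None) -> np.ndarray:
    """Signature-domain samples from a reflectance model, shape (n, len(grid))."""
    rng = _rng(seed)
    if model.flavor == "bumps":
        art = bump_articulation(
            model.grid,
            model.articulation_amplitude,
            rng,
            halfwidth=model.halfwidth,
            n=n,
        )
    else:
        art = fractal_articulation(
            model.grid,
            model.articulation_exponent,
            model.articulation_amplitude,
            rng,
            halfwidth=model.halfwidth,
            n=n,
        )
    return model.baseline()[None, :] + art


def generate_reflectance(
    model: ReflectanceModel, n: int, seed=None
) -> list[ReflectanceSpectrum]:
    """Draw reflectance instances: baseline + fractal articulation mapped back
    to the ecological domain.  All values are strictly inside (0, 1)."""
    sig = sample_signatures(model, n, seed)
    return [ReflectanceSpectrum(model.grid, g_reflectance(row)) for row in sig]


def sample_daylight_values(
    model: DaylightModel, n: int, seed=None, cmfs: Cmfs | None = None
) -> np.ndarray:
    """Daylight radiant values, shape (n, len(grid)); see generate_daylight."""
    rng = _rng(seed)
    k = model.pc_basis.shape[0] if model.pc_basis.size else 0
    log_s = np.broadcast_to(model.mean_log, (n, len(model.grid))).copy()
    if k:
        L = np.linalg.cholesky(
            np.atleast_2d(model.pc_cov) + 1e-15 * np.eye(k)
        )
        coeffs = rng.standard_normal((n, k)) @ L.T
        log_s += coeffs @ model.pc_basis
    if model.fuzz_amplitude > 0:
        log_s += fractal_articulation(
            model.grid, model.fuzz_exponent, model.fuzz_amplitude, rng, n=n
        )
    s = np.exp(log_s)
    if cmfs is not None:
        w = (s * _quad_weights(cmfs)) @ cmfs.values  # (n, 3) implied whites
        s /= w.max(axis=1, keepdims=True)
    else:
        s /= s.mean(axis=1, keepdims=True)
    return s


def _quad_weights(cmfs: Cmfs) -> np.ndarray:
    from .spectra import cell_weights

    return cell_weights(cmfs.grid)


def generate_daylight(
    model: DaylightModel, n: int, seed=None, cmfs: Cmfs | None = None
) -> list[Spectrum]:
    """Draw daylight instances: exp(mean + PC combination + fractal fuzz).

    Strictly positive by construction.  When rgb-parts ``cmfs`` are given,
    each instance is normalized so the maximum rgb coordinate of its implied
    white equals 1; otherwise to unit mean power (anchoring makes object
    colors invariant to this choice).
    """
    vals = sample_daylight_values(model, n, seed, cmfs)
    return [Spectrum(model.grid, row) for row in vals]


# ---------------------------------------------------------------------------
# database summary statistics


def _signature_matrix(ensemble) -> tuple[SpectralGrid, np.ndarray]:
    if isinstance(ensemble, np.ndarray):
        raise TypeError("pass a grid-bearing ensemble (list of spectra)")
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    grid = ensemble[0].grid
    rows = []
    for item in ensemble:
        if isinstance(item, ReflectanceSpectrum):
            rows.append(f_signature(item.values, clamp=True))
        else:  # SignatureSpectrum or Spectrum-like with .values
            rows.append(np.asarray(getattr(item, "rho", getattr(item, "values", item))))
    return grid, np.vstack(rows)


def spectral_histogram(ensemble) -> SpectralHistogram:
    """Median and quartiles per wavelength of the signature-domain ensemble."""
    grid, sig = _signature_matrix(ensemble)
    lo, med, hi = np.percentile(sig, [25, 50, 75], axis=0)
    return SpectralHistogram(grid, med, lo, hi)


def articulation_power_spectrum(
    ensemble, detrend_order: int = 1, fit_band: tuple[float, float] = (4.0, 40.0)
) -> ArticulationSpectrum:
    """Ensemble-mean periodogram of the spectral articulation.

    Each item is mapped to the signature domain, a low-order polynomial
    trend (default: mean and slope) is removed, a Hanning window applied,
    and the periodogram taken; the log-log slope is fitted over the
    mid-frequency band (default 4-40 cycles per visual range; lower bins
    carry detrending leftovers of sub-bin components and bias the fit).
    """
    if not isinstance(ensemble, np.ndarray):
        grid, sig = _signature_matrix(ensemble)
    else:
        sig = ensemble
        grid = None
    if sig.shape[0] < 10:
        raise ValueError("need at least 10 items for a stable power spectrum")
    m = sig.shape[1]
    x = np.linspace(-1.0, 1.0, m)
    V = np.vander(x, detrend_order + 1)
    coef, *_ = np.linalg.lstsq(V, sig.T, rcond=None)
    resid = sig - (V @ coef).T
    window = np.hanning(m)
    spec = np.abs(np.fft.rfft(resid * window, axis=1)) ** 2
    power = spec.mean(axis=0)[1:]
    freqs = np.arange(1, len(power) + 1, dtype=float)  # cycles per range
    band = (freqs >= fit_band[0]) & (freqs <= fit_band[1]) & (power > 0)
    slope = float(
        np.polyfit(np.log10(freqs[band]), np.log10(power[band]), 1)[0]
    )
    return ArticulationSpectrum(freqs, power, slope, fit_band)


def autocorrelation_halfwidth(articulations: np.ndarray, grid: SpectralGrid) -> float:
    """Lag (nm) where the ensemble autocorrelation first drops below 1/2.

    Computed on the raw zero-mean articulation process (no per-window mean
    removal), averaging lagged products over the ensemble.  Returns the
    maximum measurable lag when the correlation never drops that far.
    """
    x = np.asarray(articulations, dtype=float)
    m = x.shape[1]
    npad = 2 * m
    f = np.fft.rfft(x, n=npad, axis=1)
    acf = np.fft.irfft(np.abs(f) ** 2, n=npad, axis=1)[:, :m]
    counts = m - np.arange(m)
    rho = acf.mean(axis=0) / counts
    rho /= rho[0]
    below = np.nonzero(rho < 0.5)[0]
    lag = below[0] if below.size else m - 1
    return float(lag * grid.step)


# ---------------------------------------------------------------------------
# model fitting


def fit_daylight_model(database, n_pcs: int = 2) -> DaylightModel:
    """Fit the daylight model to a database of radiant spectra.

    Items are shifted to zero mean in the log domain (power normalization),
    the ensemble mean is taken, PCA retains ``n_pcs`` directions (slope,
    curvature), the coefficient covariance is estimated from the projections,
    and the residual's power-law exponent and rms give the fractal fuzz.
    """
    if len(database) < 5:
        raise ValueError("need at least 5 database items")
    if len(database) <= n_pcs:
        raise ValueError("fewer items than principal components")
    grid = database[0].grid
    logs = np.vstack([np.log(np.maximum(s.values, 1e-12)) for s in database])
    logs -= logs.mean(axis=1, keepdims=True)
    mean_log = logs.mean(axis=0)
    X = logs - mean_log
    m = X.shape[1]
    if np.allclose(X, 0.0, atol=1e-12):
        basis = np.zeros((0, m))
        return DaylightModel(grid, mean_log, basis, np.zeros((0, 0)), 4.0, 0.0)
    from sklearn.decomposition import PCA

    pca = PCA(n_components=n_pcs)
    scores = pca.fit_transform(X)
    # rescale components to unit rms so coefficient SDs are in log units
    scale = np.sqrt(np.mean(pca.components_**2, axis=1))
    basis = pca.components_ / scale[:, None]
    scores = scores * scale[None, :]
    cov = np.atleast_2d(np.cov(scores, rowvar=False))
    resid = X - scores @ basis
    amp = float(np.sqrt(np.mean(resid**2)))
    if amp < 1e-10:
        return DaylightModel(grid, mean_log, basis, cov, 4.0, 0.0)
    aps = articulation_power_spectrum(resid, detrend_order=1)
    return DaylightModel(grid, mean_log, basis, cov, -aps.slope, amp)


def fit_reflectance_model(database) -> ReflectanceModel:
    """Fit the reflectance model to a database of reflectance spectra.

    The per-wavelength mean signature becomes the baseline; the residual
    articulations give the rms amplitude, the power-law exponent and the
    autocorrelation halfwidth.
    """
    if len(database) < 5:
        raise ValueError("need at least 5 database items")
    grid, sig = _signature_matrix(database)
    baseline = sig.mean(axis=0)
    resid = sig - baseline
    amp = float(np.sqrt(np.mean(resid**2)))
    slope = float(np.polyfit(grid.wavelengths, baseline, 1)[0])
    if amp < 1e-10:
        return ReflectanceModel(
            grid, baseline_signature=baseline, baseline_slope=slope,
            articulation_amplitude=0.0,
        )
    aps = articulation_power_spectrum(resid, detrend_order=1)
    hw = autocorrelation_halfwidth(resid, grid)
    return ReflectanceModel(
        grid,
        baseline_signature=baseline,
        baseline_slope=slope,
        articulation_amplitude=amp,
        articulation_exponent=max(-aps.slope, 1.0 + 1e-6),
        correlation_halfwidth=hw,
    )
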
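"""Monte-Carlo confusion ellipsoids and the grain of object-color space.

Under ecological variation -- the daylight changing its spectrum, and the
object being replaced by any metamer of itself -- a nominally fixed object
color wanders through a small region of the rgb cube.  Summarizing each
such cloud by its 95% covariance ellipsoid and averaging the ellipsoid
volume over the cube estimates the *grain* of color space: the reciprocal
of the mean volume counts how many color categories ("distinguishing
marks") survive ecological variation, and the cube root of the mean volume
is the implied per-coordinate Weber fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .generate import (
    DaylightModel,
    ReflectanceModel,
    sample_daylight_values,
)
from .metamers import max_scale, random_black
from .solid import CanonicalBasis, canonical_spectrum
from .spectra import (
    Cmfs,
    ObjectColor,
    ReflectanceSpectrum,
    Spectrum,
    cell_weights,
    resample,
)

__all__ = [
    "ConfusionEllipsoid",
    "GrainSummary",
    "covariance_ellipsoid",
    "equivalent_radius",
    "maximum_radius",
    "illuminant_variation_grain",
    "metamerism_grain",
    "grain_field",
    "interior_lattice",
    "coordinate_grain",
]

#: Eigenvalue floor guarding degenerate covariances.
EIG_FLOOR = 1e-18


@dataclass(frozen=True)
class ConfusionEllipsoid:
    """95% covariance ellipsoid of a cloud of object colors."""

    center: np.ndarray
    covariance: np.ndarray
    level: float
    semiaxes: np.ndarray  # sorted ascending
    volume: float
    degenerate: bool = False


@dataclass(frozen=True)
class GrainSummary:
    """Field summary: radius quartiles/ranges, mean volume, mark count."""

    ellipsoids: list[ConfusionEllipsoid]
    equivalent_radius_quartiles: tuple[float, float, float]
    equivalent_radius_range: tuple[float, float]
    maximum_radius_quartiles: tuple[float, float, float]
    maximum_radius_range: tuple[float, float]
    mean_volume: float
    n_marks: float

    @classmethod
    def from_ellipsoids(cls, ellipsoids: list[ConfusionEllipsoid]) -> "GrainSummary":
        eq = np.array([equivalent_radius(e) for e in ellipsoids])
        mx = np.array([maximum_radius(e) for e in ellipsoids])
        vol = float(np.mean([e.volume for e in ellipsoids]))
        return cls(
            ellipsoids=ellipsoids,
            equivalent_radius_quartiles=tuple(np.percentile(eq, [25, 50, 75])),
            equivalent_radius_range=(float(eq.min()), float(eq.max())),
            maximum_radius_quartiles=tuple(np.percentile(mx, [25, 50, 75])),
            maximum_radius_range=(float(mx.min()), float(mx.max())),
            mean_volume=vol,
            n_marks=(1.0 / vol if vol > 0 else np.inf),
        )


def covariance_ellipsoid(points, level: float = 0.95) -> ConfusionEllipsoid:
    """Sample-covariance ellipsoid at the given confidence level.

    Semiaxes are the square roots of the covariance eigenvalues scaled by
    the chi-square quantile with 3 degrees of freedom (about 7.815 at 95%).
    Fewer than 4 points, or a coplanar cloud, give a degenerate ellipsoid
    with zero volume (flagged); fewer than 2 points raise.
    """
    pts = np.asarray(
        [p.as_array() if isinstance(p, ObjectColor) else p for p in points],
        dtype=float,
    )
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be an iterable of 3-vectors")
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    eig = np.linalg.eigvalsh(cov)
    eig = np.clip(eig, 0.0, None)
    q = chi2.ppf(level, df=3)
    semi = np.sqrt(eig * q)
    degenerate = pts.shape[0] < 4 or eig.min() <= EIG_FLOOR
    volume = 0.0 if degenerate and eig.min() <= EIG_FLOOR else float(
        4.0 / 3.0 * np.pi * np.prod(semi)
    )
    return ConfusionEllipsoid(
        center=center,
        covariance=cov,
        level=level,
        semiaxes=semi,
        volume=volume,
        degenerate=degenerate,
    )


def equivalent_radius(e: ConfusionEllipsoid) -> float:
    """Radius of the sphere with the same volume as the ellipsoid."""
    return float((e.volume * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0))


def maximum_radius(e: ConfusionEllipsoid) -> float:
    """The maximum semiaxis of the ellipsoid."""
    return float(e.semiaxes.max())


def coordinate_grain(n_colors: float) -> float:
    """Per-coordinate grain implied by a count of distinguishable colors.

    The cube root of the reciprocal count: a million colors imply a
    coordinate uncertainty of 0.01 in the unit rgb cube.
    """
    if n_colors <= 0:
        raise ValueError("count must be positive")
    return float((1.0 / n_colors) ** (1.0 / 3.0))


# ---------------------------------------------------------------------------
# pipelines


def _anchored_colors(
    F_values: np.ndarray, I_values: np.ndarray, cmfs: Cmfs
) -> np.ndarray:
    """White-anchored rgb colors for reflectance rows under illuminant rows.

    Shapes: F (m,) or (k, m); I (m,) or (k, m); broadcast to per-row pairs.
    """
    A = cell_weights(cmfs.grid)[:, None] * cmfs.values  # (m, 3)
    F_values = np.atleast_2d(F_values)
    I_values = np.atleast_2d(I_values)
    white = I_values @ A
    beam = (F_values * I_values) @ A
    return beam / white


def illuminant_variation_grain(
    objects: list[ReflectanceSpectrum],
    illuminants: list[Spectrum],
    cmfs: Cmfs,
    level: float = 0.95,
) -> GrainSummary:
    """All objects under all illuminants: one confusion ellipsoid per object.

    White anchoring is recomputed per illuminant, so the white object (and
    the whole black-white diagonal) is invariant and gets a zero-volume
    ellipsoid.
    """
    if not objects or not illuminants:
        raise ValueError("need nonempty object and illuminant ensembles")
    Fs = np.vstack([resample(F, cmfs.grid).values for F in objects])
    Is = np.vstack([resample(I, cmfs.grid).values for I in illuminants])
    A = cell_weights(cmfs.grid)[:, None] * cmfs.values
    whites = Is @ A  # (k, 3)
    ellipsoids = []
    for f in Fs:
        beams = (f[None, :] * Is) @ A
        colors = beams / whites
        ellipsoids.append(covariance_ellipsoid(colors, level))
    return GrainSummary.from_ellipsoids(ellipsoids)


def metamerism_grain(
    fiducials,
    n_samples: int,
    reflectance_model: ReflectanceModel,
    daylight_model: DaylightModel,
    cmfs: Cmfs,
    basis: CanonicalBasis,
    seed=None,
    level: float = 0.95,
    scaling: str = "max",
) -> GrainSummary:
    """Metamerism + illuminant variation: the full ecological confusion field.

    Per fiducial color and per sample: perturb the canonical spectrum with a
    maximally scaled random metameric black, draw a fresh daylight instance,
    and recompute the white-anchored color under it.  Boundary fiducials
    have no metamers and are skipped with a warning.
    """
    import warnings

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ellipsoids = []
    for c in fiducials:
        rgb = np.asarray(c, dtype=float)
        if np.any(rgb <= 0.0) or np.any(rgb >= 1.0):
            warnings.warn(f"skipping boundary fiducial {tuple(rgb)}: no metamers")
            continue
        base = canonical_spectrum(ObjectColor(*rgb), basis)
        Is = sample_daylight_values(daylight_model, n_samples, rng, cmfs=cmfs)
        Fs = np.empty((n_samples, len(cmfs.grid)))
        for i in range(n_samples):
            black = random_black(reflectance_model, basis.illuminant, cmfs, rng)
            s = max_scale(black, base)
            if scaling == "uniform":
                s = float(rng.uniform(0.0, s))
            Fs[i] = np.clip(base.values + s * black.delta, 0.0, 1.0)
        colors = _anchored_colors(Fs, Is, cmfs)
        ellipsoids.append(covariance_ellipsoid(colors, level))
    if not ellipsoids:
        raise ValueError("no interior fiducials")
    return GrainSummary.from_ellipsoids(ellipsoids)


def interior_lattice(spacing: float = 0.25) -> list[ObjectColor]:
    """Regular lattice of interior fiducial colors in the unit cube."""
    ticks = np.arange(spacing, 1.0 - spacing / 2.0, spacing)
    ticks = ticks[(ticks > 0.0) & (ticks < 1.0)]
    if len(ticks) == 0:
        raise ValueError("spacing leaves no interior fiducials")
    return [
        ObjectColor(float(r), float(g), float(b))
        for r in ticks
        for g in ticks
        for b in ticks
    ]


def grain_field(
    grid_spacing: float,
    n_samples: int,
    reflectance_model: ReflectanceModel,
    daylight_model: DaylightModel,
    cmfs: Cmfs,
    basis: CanonicalBasis,
    seed=None,
    **kwargs,
) -> GrainSummary:
    """The confusion-ellipsoid field over a regular interior cube lattice."""
    fiducials = interior_lattice(grid_spacing)
    return metamerism_grain(
        fiducials,
        n_samples,
        reflectance_model,
        daylight_model,
        cmfs,
        basis,
        seed=seed,
        **kwargs,
    )
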
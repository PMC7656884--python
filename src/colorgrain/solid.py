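"""The Schrodinger color solid and its largest inscribed crate.

The colors of all beams dominated by a standard illuminant D form a convex
body, the color solid.  Its boundary colors come from "optimal" spectra
chi(lambda) * D(lambda) with chi a 0/1 characteristic function having at
most two transitions (band or band-stop).  The largest parallelepiped
("crate") inscribed in the solid with a vertex at black turns out to be
spanned by the colors of a *tripartition* of the illuminant into a blue,
green and red part, cut at two loci (lambda1, lambda2).  Those three part
colors define the rgb object-color basis: the crate becomes the unit cube,
white is (1,1,1), and every color in the cube has a unique three-level
"canonical" reflectance spectrum metameric to it.

Cut positions are continuous: a cut inside a sample cell assigns the cell's
quadrature mass fractionally to the two sides (area weighting), so cut loci
are meaningful at sub-nm resolution while every integral stays exactly
consistent with :func:`colorgrain.spectra.tristimulus`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .spectra import (
    Cmfs,
    ObjectColor,
    SpectralGrid,
    Spectrum,
    ReflectanceSpectrum,
    cell_weights,
    resample,
)

__all__ = [
    "BinarySpectrum",
    "Tripartition",
    "CanonicalBasis",
    "ColorSolidMesh",
    "band_occupancy",
    "optimal_spectrum",
    "solid_boundary",
    "solid_volume",
    "crate_volume",
    "part_matrix",
    "find_largest_crate",
    "canonical_basis",
    "rgb_cmfs",
    "canonical_spectrum",
    "cardinal_colors",
    "CARDINAL_LABELS",
]


@dataclass(frozen=True)
class BinarySpectrum:
    """A 0/1 characteristic function chi(lambda) on a grid."""

    grid: SpectralGrid
    chi: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.chi, dtype=float)
        if v.shape != (len(self.grid),):
            raise ValueError("chi length must match grid")
        if not np.all((v == 0.0) | (v == 1.0)):
            raise ValueError("chi must be 0 or 1 at every sample")
        v.setflags(write=False)
        object.__setattr__(self, "chi", v)

    @property
    def transitions(self) -> int:
        """Number of 0 <-> 1 changes along the grid."""
        return int(np.sum(self.chi[1:] != self.chi[:-1]))


@dataclass(frozen=True)
class Tripartition:
    """Two cut loci splitting the visual range into blue/green/red parts."""

    lambda1: float
    lambda2: float
    grid: SpectralGrid

    def __post_init__(self) -> None:
        if not (
            self.grid.lambda_uv < self.lambda1 < self.lambda2 < self.grid.lambda_ir
        ):
            raise ValueError(
                "cut loci must satisfy lambda_uv < lambda1 < lambda2 < lambda_ir"
            )


@dataclass(frozen=True)
class CanonicalBasis:
    """The three parts of the illuminant and their colors.

    ``parts`` are the blue, green and red part beams (in that order); they
    sum to the illuminant exactly at every sample.  ``part_colors`` is the
    3x3 matrix whose columns are the xyz tristimulus vectors of the parts;
    it is the change-of-basis matrix from rgb crate coordinates to xyz.
    """

    tripartition: Tripartition
    illuminant: Spectrum
    parts: tuple[Spectrum, Spectrum, Spectrum]
    part_colors: np.ndarray  # columns: blue, green, red in xyz

    @property
    def matrix(self) -> np.ndarray:
        """Columns (B, G, R) reordered to map rgb -> xyz: [R G B]."""
        return self.part_colors[:, ::-1]


@dataclass(frozen=True)
class ColorSolidMesh:
    """Boundary colors of the solid: all band/band-stop optimal spectra."""

    points: np.ndarray  # (m, 3) xyz tristimulus values
    resolution: int
    _hull: ConvexHull | None = field(default=None, repr=False, compare=False)

    @property
    def hull(self) -> ConvexHull:
        h = self._hull
        if h is None:
            h = ConvexHull(self.points)
            object.__setattr__(self, "_hull", h)
        return h


# ---------------------------------------------------------------------------
# continuous-cut quadrature


def band_occupancy(grid: SpectralGrid, la, lb) -> np.ndarray:
    """Fraction of each sample cell covered by the band [la, lb).

    Cells are ``[lambda_i - step/2, lambda_i + step/2]`` clipped to the grid
    limits; multiplying occupancies by the trapezoid weights of
    :func:`cell_weights` gives exact piecewise-linear partial integrals.
    ``la``/``lb`` may be arrays (broadcast against each other); the result
    has shape ``broadcast(la, lb).shape + (len(grid),)``.
    """
    la = np.asarray(la, dtype=float)[..., None]
    lb = np.asarray(lb, dtype=float)[..., None]
    wl = grid.wavelengths
    lo = np.maximum(wl - grid.step / 2.0, grid.lambda_uv)
    hi = np.minimum(wl + grid.step / 2.0, grid.lambda_ir)
    occ = (np.minimum(lb, hi) - np.maximum(la, lo)) / (hi - lo)
    return np.clip(occ, 0.0, 1.0)


def _weighted(illuminant: Spectrum, cmfs: Cmfs) -> tuple[np.ndarray, np.ndarray]:
    """(w * D * cmf) rows and their total; shared by all partial integrals."""
    D = resample(illuminant, cmfs.grid)
    y = (D.values * cell_weights(cmfs.grid))[:, None] * cmfs.values
    return y, y.sum(axis=0)


class _CumulativeTristimulus:
    """Exact partial tristimulus of chi(lambda) * D(lambda) for continuous cuts.

    The integrand D * cmf is treated as piecewise linear between samples
    (the continuum limit of the trapezoid rule): the cumulative integral is
    piecewise quadratic in the cut position, so the crate objective has
    genuine interior optima and cut loci are meaningful at sub-nm
    resolution.  The full-range total coincides with the trapezoid rule
    exactly.
    """

    def __init__(self, illuminant: Spectrum, cmfs: Cmfs) -> None:
        D = resample(illuminant, cmfs.grid)
        self.grid = cmfs.grid
        self.y = D.values[:, None] * cmfs.values  # integrand at samples
        h = cmfs.grid.step
        self.nodes = np.concatenate(
            [np.zeros((1, 3)), np.cumsum(0.5 * h * (self.y[1:] + self.y[:-1]), axis=0)]
        )
        self.total = self.nodes[-1]

    def cumulative(self, lam) -> np.ndarray:
        """Integral of D * cmf over [lambda_uv, lam]; lam may be an array."""
        lam = np.asarray(lam, dtype=float)
        wl = self.grid.wavelengths
        h = self.grid.step
        i = np.clip(((lam - wl[0]) // h).astype(int), 0, len(wl) - 2)
        t = (lam - wl[i])[..., None]
        return self.nodes[i] + self.y[i] * t + (self.y[i + 1] - self.y[i]) * t**2 / (2 * h)

    def band(self, la, lb) -> np.ndarray:
        return self.cumulative(lb) - self.cumulative(la)


# ---------------------------------------------------------------------------
# operations


def optimal_spectrum(kind: str, la: float, lb: float, grid: SpectralGrid) -> BinarySpectrum:
    """A Schrodinger optimal spectrum: band pass or band stop between cuts.

    ``band`` is 1 on [la, lb) and 0 elsewhere; ``band_stop`` is the
    complement.  Sampled at the grid points (transition count <= 2).
    """
    if kind not in ("band", "band_stop"):
        raise ValueError("kind must be 'band' or 'band_stop'")
    if not (grid.lambda_uv <= la <= lb <= grid.lambda_ir):
        raise ValueError("cuts must lie inside the grid limits with la <= lb")
    wl = grid.wavelengths
    mask = (wl >= la) & (wl < lb)
    if lb >= grid.lambda_ir:  # a band reaching the red limit includes it
        mask |= wl == wl[-1]
    chi = mask.astype(float)
    if kind == "band_stop":
        chi = 1.0 - chi
    return BinarySpectrum(grid, chi)


def solid_boundary(illuminant: Spectrum, cmfs: Cmfs, n: int = 100) -> ColorSolidMesh:
    """Boundary mesh: colors of band and band-stop spectra on an n x n cut lattice.

    Includes black (empty band) and white (full band).
    """
    if n < 2:
        raise ValueError("need n >= 2 cut positions per axis")
    cum = _CumulativeTristimulus(illuminant, cmfs)
    grid = cmfs.grid
    cuts = np.linspace(grid.lambda_uv, grid.lambda_ir, n)
    A, B = np.meshgrid(cuts, cuts, indexing="ij")
    keep = A <= B
    band = cum.band(A[keep], B[keep])
    stop = cum.total[None, :] - band
    pts = np.vstack([band, stop])
    return ColorSolidMesh(points=pts, resolution=n)


def solid_volume(illuminant: Spectrum, cmfs: Cmfs, n: int = 100) -> float:
    """Convex-hull volume of the color solid boundary mesh (basis units^3)."""
    mesh = solid_boundary(illuminant, cmfs, n)
    try:
        return float(mesh.hull.volume)
    except QhullError as exc:  # coplanar / degenerate mesh
        raise ValueError("degenerate color solid (coplanar boundary mesh)") from exc


def part_matrix(illuminant: Spectrum, cmfs: Cmfs, t: Tripartition) -> np.ndarray:
    """3x3 matrix with columns = tristimulus of the blue, green, red parts."""
    cum = _CumulativeTristimulus(illuminant, cmfs)
    grid = cmfs.grid
    edges_lo = np.array([grid.lambda_uv, t.lambda1, t.lambda2])
    edges_hi = np.array([t.lambda1, t.lambda2, grid.lambda_ir])
    return cum.band(edges_lo, edges_hi).T


def crate_volume(illuminant: Spectrum, cmfs: Cmfs, t: Tripartition) -> float:
    """Volume of the crate spanned by the three part colors (|det|)."""
    return float(abs(np.linalg.det(part_matrix(illuminant, cmfs, t))))


def find_largest_crate(
    illuminant: Spectrum,
    cmfs: Cmfs,
    coarse_step: float = 1.0,
    tie_tol: float = 1e-6,
) -> Tripartition:
    """Exhaustive search plus local refinement for the volume-maximizing crate.

    A coarse lattice scan at ``coarse_step`` nm locates the global basin;
    nested lattice refinement (each level 10x finer) then pins the
    continuous cut loci to sub-nm precision -- robust to the kinks of the
    piecewise-polynomial objective at sample-cell edges.  If two
    well-separated lattice candidates tie within ``tie_tol`` (relative) and
    refine to distinct optima of equal volume, a ValueError reports both.
    """
    grid = cmfs.grid
    cum = _CumulativeTristimulus(illuminant, cmfs)
    total = cum.total

    def vol_lattice(l1s: np.ndarray, l2s: np.ndarray):
        """|det| on the product lattice l1s x l2s (invalid pairs -> 0)."""
        cum1 = cum.cumulative(l1s)
        cum2 = cum.cumulative(l2s)
        M = np.empty((len(l1s), len(l2s), 3, 3))
        M[..., 0] = cum1[:, None, :]
        M[..., 1] = cum2[None, :, :] - cum1[:, None, :]
        M[..., 2] = total[None, None, :] - cum2[None, :, :]
        v = np.abs(np.linalg.det(M))
        v[l1s[:, None] >= l2s[None, :]] = 0.0
        return v

    def refine(l1, l2):
        step = coarse_step
        for _ in range(5):  # down to coarse_step * 1e-5
            l1s = np.clip(
                l1 + step * np.linspace(-1.5, 1.5, 31),
                grid.lambda_uv + 1e-9,
                grid.lambda_ir - 1e-9,
            )
            l2s = np.clip(
                l2 + step * np.linspace(-1.5, 1.5, 31),
                grid.lambda_uv + 1e-9,
                grid.lambda_ir - 1e-9,
            )
            v = vol_lattice(l1s, l2s)
            a, b = np.unravel_index(v.argmax(), v.shape)
            l1, l2 = l1s[a], l2s[b]
            step /= 10.0
        return np.array([l1, l2]), v[a, b]

    cuts = np.arange(
        grid.lambda_uv + coarse_step, grid.lambda_ir - coarse_step / 2, coarse_step
    )
    vgrid = vol_lattice(cuts, cuts)
    flat = vgrid.ravel()
    order = np.argsort(flat)[::-1]
    vmax = flat[order[0]]
    i, j = np.unravel_index(order, vgrid.shape)
    vols = flat
    best = refine(cuts[i[0]], cuts[j[0]])
    # tie detection: a near-equal coarse candidate far from the winner
    for rank in range(1, len(order)):
        if vols[order[rank]] < (1.0 - tie_tol) * vmax:
            break
        cand = (cuts[i[rank]], cuts[j[rank]])
        if np.hypot(cand[0] - best[0][0], cand[1] - best[0][1]) > 4 * coarse_step:
            other = refine(*cand)
            if (
                abs(other[1] - best[1]) <= tie_tol * best[1]
                and np.hypot(*(other[0] - best[0])) > 4 * coarse_step
            ):
                raise ValueError(
                    f"non-unique largest crate: candidates {best[0]} and {other[0]}"
                )
    l1, l2 = best[0]
    if l1 > l2:  # tie-break convention: smaller lambda1 first
        l1, l2 = l2, l1
    return Tripartition(float(l1), float(l2), grid)


def canonical_basis(illuminant: Spectrum, t: Tripartition, cmfs: Cmfs) -> CanonicalBasis:
    """Split the illuminant into its blue, green and red part beams.

    The sampled parts use fractional occupancy at the cut cells, so they sum
    to the illuminant exactly at every sample, and their trapezoid
    tristimulus values are exactly the columns of ``part_colors`` (which
    therefore agree with :func:`part_matrix` to O(step^2)).
    """
    grid = cmfs.grid
    D = resample(illuminant, cmfs.grid)
    occ_b = band_occupancy(grid, grid.lambda_uv, t.lambda1)
    occ_r = band_occupancy(grid, t.lambda2, grid.lambda_ir)
    blue = occ_b * D.values
    red = occ_r * D.values
    green = D.values - blue - red  # exact residual of the partition
    parts = (Spectrum(grid, blue), Spectrum(grid, np.clip(green, 0, None)), Spectrum(grid, red))
    w = cell_weights(grid)
    M = np.column_stack([(p.values * w) @ cmfs.values for p in parts])
    return CanonicalBasis(
        tripartition=t, illuminant=D, parts=parts, part_colors=M
    )


def rgb_cmfs(basis: CanonicalBasis, cmfs: Cmfs) -> Cmfs:
    """Re-express xyz CMFs in the rgb-parts basis of a canonical basis.

    The returned functions assign each part beam a unit coordinate vector:
    red part -> (1,0,0), green -> (0,1,0), blue -> (0,0,1).
    """
    if cmfs.basis != "xyz":
        raise ValueError("expected xyz CMFs")
    Minv = np.linalg.inv(basis.matrix)  # xyz -> rgb
    return Cmfs(cmfs.grid, cmfs.values @ Minv.T, basis="rgb-parts")


def canonical_spectrum(c: ObjectColor, basis: CanonicalBasis) -> ReflectanceSpectrum:
    """The unique three-level reflectance metameric to an rgb-cube color.

    Level ``r`` on the red part of the spectrum, ``g`` on the green part and
    ``b`` on the blue part (fractional at the cut cells).  Coordinates
    outside [0, 1] have no canonical representation inside the crate.
    """
    rgb = np.asarray(c, dtype=float)
    if np.any(rgb < 0) or np.any(rgb > 1):
        raise ValueError("no canonical representation outside the unit cube")
    grid = basis.illuminant.grid
    t = basis.tripartition
    lo = np.array([grid.lambda_uv, t.lambda1, t.lambda2])
    hi = np.array([t.lambda1, t.lambda2, grid.lambda_ir])
    occ = band_occupancy(grid, lo, hi)  # rows: blue, green, red
    values = rgb[::-1] @ occ  # b*blue + g*green + r*red
    return ReflectanceSpectrum(grid, np.clip(values, 0.0, 1.0))


CARDINAL_LABELS = {
    "k": (0.0, 0.0, 0.0),
    "r": (1.0, 0.0, 0.0),
    "g": (0.0, 1.0, 0.0),
    "b": (0.0, 0.0, 1.0),
    "c": (0.0, 1.0, 1.0),
    "m": (1.0, 0.0, 1.0),
    "y": (1.0, 1.0, 0.0),
    "w": (1.0, 1.0, 1.0),
}


def cardinal_colors(basis: CanonicalBasis) -> dict[str, ObjectColor]:
    """The eight cube vertices: black, white, primaries and secondaries.

    Supplementary pairs (r+c, g+m, b+y, k+w) add to white; all eight lie on
    the boundary of the color solid.
    """
    return {k: ObjectColor(*v) for k, v in CARDINAL_LABELS.items()}
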
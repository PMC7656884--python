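"""Constructive proof that colors are not object properties.

Two radiant sources are built that are exactly metameric to the standard
daylight (they differ by a radiant metameric black), so a white daisy --
and any observer anchoring on it -- reports both as ordinary white light.
Yet two physical reflectances ("rose" and "violet") are constructed whose
object colors *swap* between the two sources: the rose shows the red target
color under the first source and the blue target under the second, the
violet the other way round.  The swap exploits only metamerism, the human
blind spot for spectral fine structure.

The construction is a constrained inverse problem: reflectances are
expanded in a smooth Gaussian-bump basis (plus a constant), the source
modulation lives in the null space of the tristimulus operator, and a
bounded least-squares solve enforces the six color equations together with
pointwise physicality 0 <= F <= 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .solid import CanonicalBasis
from .spectra import (
    Cmfs,
    ObjectColor,
    ReflectanceSpectrum,
    SpectralGrid,
    Spectrum,
    cell_weights,
)

__all__ = ["HueSwapExhibit", "construct_hue_swap", "verify_exhibit"]


@dataclass(frozen=True)
class HueSwapExhibit:
    """Two metameric 'white' sources and the rose/violet/daisy reflectances."""

    illuminant_1: Spectrum
    illuminant_2: Spectrum
    rose: ReflectanceSpectrum
    violet: ReflectanceSpectrum
    daisy: ReflectanceSpectrum
    colors: dict  # (object name, illuminant index) -> ObjectColor
    target_red: ObjectColor
    target_blue: ObjectColor
    residual: float


def _bump_basis(grid: SpectralGrid, n_bumps: int = 20, with_constant: bool = True):
    wl = grid.wavelengths
    centers = np.linspace(grid.lambda_uv, grid.lambda_ir, n_bumps)
    sigma = (grid.lambda_ir - grid.lambda_uv) / (n_bumps - 1) * 1.2
    phi = np.exp(-((wl[:, None] - centers[None, :]) ** 2) / (2 * sigma**2))
    if with_constant:
        phi = np.column_stack([np.ones(len(wl)), phi])
    return phi


def _anchored_operator(I_values: np.ndarray, cmfs_rgb: Cmfs) -> np.ndarray:
    """(3, m) map: reflectance values -> white-anchored rgb color under I."""
    A = cell_weights(cmfs_rgb.grid)[:, None] * cmfs_rgb.values  # (m, 3)
    white = I_values @ A
    return (I_values[:, None] * A).T / white[:, None]


def construct_hue_swap(
    cmfs_rgb: Cmfs | None = None,
    standard_illuminant: Spectrum | None = None,
    target_red: ObjectColor = ObjectColor(0.7, 0.2, 0.2),
    target_blue: ObjectColor = ObjectColor(0.2, 0.3, 0.7),
    tol: float = 1e-3,
    modulation_depth: float = 0.92,
    modulation_cycles: float = 5.0,
    n_bumps: int = 32,
) -> HueSwapExhibit:
    """Build the color-swap exhibit for a pair of target colors.

    Both sources are the standard beam plus a radiant metameric black: a
    smooth relative modulation ``mod`` with exactly zero tristimulus gives
    ``I1 = D (1 - mod)`` and ``I2 = D (1 + mod)``, so each is metameric to
    the standard daylight (a white daisy looks identical under all three).
    Symmetric modulation is essential: with one source left unmodulated the
    per-component color ratio between the sources is bounded by
    ``(1 + depth)``, which rules out strong swaps; symmetrically it is
    ``(1 + depth) / (1 - depth)``.  The modulation must also change sign
    *within* each part of the spectrum (hence several cycles), because rose
    and violet need opposite effective modulation on the same coordinate.
    Rose and violet are then solved as bounded least squares over the
    smooth bump basis so that their anchored colors hit (red, blue) and
    (blue, red) under the two sources.  Raises when the physical
    constraints leave a residual above ``tol``.
    """
    from . import fixtures

    if cmfs_rgb is None:
        cmfs_rgb = fixtures.standard_rgb_cmfs()
    grid = cmfs_rgb.grid
    D = standard_illuminant or fixtures.d65(grid)
    Dv = D.values

    tr = np.asarray(target_red, float)
    tb = np.asarray(target_blue, float)
    if np.any((tr <= 0) | (tr >= 1)) or np.any((tb <= 0) | (tb >= 1)):
        raise ValueError("targets must lie strictly inside the unit cube")
    if np.allclose(tr, tb):
        raise ValueError("targets must be distinct")

    # --- source modulation: a smooth radiant metameric black -------------
    phi = _bump_basis(grid, n_bumps, with_constant=False)
    A = cell_weights(grid)[:, None] * cmfs_rgb.values
    B = phi.T @ (Dv[:, None] * A)  # (n_bumps, 3): color of D * bump_j
    _, _, vt = np.linalg.svd(B.T, full_matrices=True)
    null = vt[3:].T  # (n_bumps, n_bumps - 3)
    wl = grid.wavelengths
    shape = np.sin(2.0 * np.pi * modulation_cycles * (wl - grid.lambda_uv) / grid.width)
    a0, *_ = np.linalg.lstsq(phi, shape, rcond=None)
    a_null = null @ (null.T @ a0)
    mod = phi @ a_null
    mod *= modulation_depth / np.abs(mod).max()
    I1v = Dv * (1.0 - mod)
    I2v = Dv * (1.0 + mod)
    I1 = Spectrum(grid, I1v)
    I2 = Spectrum(grid, I2v)

    # --- reflectance solves ----------------------------------------------
    P1 = _anchored_operator(I1v, cmfs_rgb)
    P2 = _anchored_operator(I2v, cmfs_rgb)
    psi = _bump_basis(grid, n_bumps, with_constant=True)
    E = np.vstack([P1 @ psi, P2 @ psi])  # (6, k)
    thin = psi[::4]  # physicality constraints on a thinned sample set
    eps = 1e-3

    def solve(t1: np.ndarray, t2: np.ndarray) -> tuple[np.ndarray, float]:
        t = np.concatenate([t1, t2])
        x0, *_ = np.linalg.lstsq(E, t, rcond=None)

        def cost(a):
            r = E @ a - t
            return float(r @ r + 1e-8 * a @ a)

        def jac(a):
            return 2.0 * (E.T @ (E @ a - t)) + 2e-8 * a

        cons = [
            {"type": "ineq", "fun": lambda a: thin @ a - eps, "jac": lambda a: thin},
            {"type": "ineq", "fun": lambda a: 1 - eps - thin @ a, "jac": lambda a: -thin},
        ]
        res = minimize(
            cost, x0, jac=jac, method="SLSQP", constraints=cons,
            options={"maxiter": 400, "ftol": 1e-14},
        )
        F = np.clip(psi @ res.x, 0.0, 1.0)
        resid = float(
            max(
                np.abs(P1 @ F - t1).max(),
                np.abs(P2 @ F - t2).max(),
            )
        )
        return F, resid

    rose_v, r_rose = solve(tr, tb)
    violet_v, r_violet = solve(tb, tr)
    residual = max(r_rose, r_violet)
    if residual > tol:
        raise ValueError(
            f"targets infeasible under physical constraints: best residual {residual:.2e}"
        )

    rose = ReflectanceSpectrum(grid, rose_v)
    violet = ReflectanceSpectrum(grid, violet_v)
    daisy = ReflectanceSpectrum(grid, np.ones(len(grid)))
    colors = {}
    for name, F in (("rose", rose), ("violet", violet), ("daisy", daisy)):
        for idx, P in ((1, P1), (2, P2)):
            colors[(name, idx)] = ObjectColor(*(P @ F.values))
    return HueSwapExhibit(
        illuminant_1=I1,
        illuminant_2=I2,
        rose=rose,
        violet=violet,
        daisy=daisy,
        colors=colors,
        target_red=ObjectColor(*tr),
        target_blue=ObjectColor(*tb),
        residual=residual,
    )


def verify_exhibit(
    e: HueSwapExhibit,
    cmfs_rgb: Cmfs | None = None,
    tol: float = 1e-3,
    metamerism_tol: float = 1e-6,
) -> dict:
    """Independently recompute all six colors and check every invariant.

    Returns a machine-readable report: pass/fail per clause plus the
    measured residuals.
    """
    from . import fixtures

    if cmfs_rgb is None:
        cmfs_rgb = fixtures.standard_rgb_cmfs()
    A = cell_weights(cmfs_rgb.grid)[:, None] * cmfs_rgb.values
    t1 = e.illuminant_1.values @ A
    t2 = e.illuminant_2.values @ A
    met_resid = float(np.linalg.norm(t1 - t2) / np.linalg.norm(t1))

    P1 = _anchored_operator(e.illuminant_1.values, cmfs_rgb)
    P2 = _anchored_operator(e.illuminant_2.values, cmfs_rgb)

    def color(F, P):
        return P @ F.values

    daisy1 = color(e.daisy, P1)
    daisy2 = color(e.daisy, P2)
    swap_1 = float(np.abs(color(e.rose, P1) - color(e.violet, P2)).max())
    swap_2 = float(np.abs(color(e.rose, P2) - color(e.violet, P1)).max())
    target_resid = float(
        max(
            np.abs(color(e.rose, P1) - np.asarray(e.target_red)).max(),
            np.abs(color(e.rose, P2) - np.asarray(e.target_blue)).max(),
            np.abs(color(e.violet, P1) - np.asarray(e.target_blue)).max(),
            np.abs(color(e.violet, P2) - np.asarray(e.target_red)).max(),
        )
    )
    physical = bool(
        np.all(e.illuminant_1.values >= 0)
        and np.all(e.illuminant_2.values >= 0)
        and all(
            np.all((F.values >= 0) & (F.values <= 1))
            for F in (e.rose, e.violet, e.daisy)
        )
    )
    report = {
        "metameric_sources": met_resid <= metamerism_tol,
        "metamerism_residual": met_resid,
        "daisy_white_both": bool(
            np.allclose(daisy1, 1.0, atol=1e-9) and np.allclose(daisy2, 1.0, atol=1e-9)
        ),
        "swap": swap_1 <= 2 * tol and swap_2 <= 2 * tol,
        "swap_residuals": (swap_1, swap_2),
        "targets_hit": target_resid <= tol,
        "target_residual": target_resid,
        "physical": physical,
    }
    report["passed"] = all(
        report[k] for k in ("metameric_sources", "daisy_white_both", "swap", "targets_hit", "physical")
    )
    return report
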
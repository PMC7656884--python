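"""Confusion ellipsoids and the graininess pipelines."""

import numpy as np
import pytest
from scipy.stats import chi2

from colorgrain.generate import DaylightModel, ReflectanceModel, generate_reflectance
from colorgrain.grain import (
    ConfusionEllipsoid,
    coordinate_grain,
    covariance_ellipsoid,
    equivalent_radius,
    grain_field,
    illuminant_variation_grain,
    interior_lattice,
    maximum_radius,
    metamerism_grain,
)
from colorgrain.spectra import ObjectColor, ReflectanceSpectrum, Spectrum


class TestCovarianceEllipsoid:
    def test_identical_points_give_zero_volume(self):
        e = covariance_ellipsoid([np.array([0.2, 0.3, 0.4])] * 10)
        assert e.volume == 0.0
        assert equivalent_radius(e) == 0.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            covariance_ellipsoid([np.zeros(3)])

    def test_isotropic_gaussian_matches_closed_form(self, rng):
        pts = rng.normal(0.5, 0.01, size=(100_000, 3))
        e = covariance_ellipsoid(pts, level=0.95)
        r_true = 0.01 * np.sqrt(chi2.ppf(0.95, 3))
        assert abs(equivalent_radius(e) / r_true - 1) < 0.02
        assert abs(maximum_radius(e) / r_true - 1) < 0.02

    def test_anisotropic_semiaxes_recover_imposed_sds(self, rng):
        sds = np.array([0.005, 0.01, 0.04])
        pts = rng.normal(0, 1, size=(50_000, 3)) * sds
        e = covariance_ellipsoid(pts)
        ratio = np.sort(e.semiaxes) / np.sort(sds)
        assert np.abs(ratio / ratio[0] - 1).max() < 0.05

    def test_volume_formula_consistency(self, rng):
        pts = rng.normal(0, 0.02, size=(5000, 3))
        e = covariance_ellipsoid(pts)
        assert np.isclose(e.volume, 4 / 3 * np.pi * np.prod(e.semiaxes))


class TestRadii:
    def test_sphere_radii_coincide(self):
        e = ConfusionEllipsoid(
            np.zeros(3), np.eye(3), 0.95, np.full(3, 0.02),
            4 / 3 * np.pi * 0.02**3,
        )
        assert np.isclose(equivalent_radius(e), 0.02)
        assert np.isclose(maximum_radius(e), 0.02)

    def test_elongated_ellipsoid(self):
        a = 0.01
        semi = np.array([a, a, 8 * a])
        e = ConfusionEllipsoid(np.zeros(3), np.eye(3), 0.95, semi,
                               4 / 3 * np.pi * np.prod(semi))
        assert np.isclose(maximum_radius(e), 8 * a)
        assert np.isclose(equivalent_radius(e), 2 * a)

    def test_equivalent_never_exceeds_maximum(self, rng):
        for _ in range(1000):
            semi = rng.uniform(0.001, 0.1, 3)
            e = ConfusionEllipsoid(np.zeros(3), np.eye(3), 0.95, semi,
                                   4 / 3 * np.pi * np.prod(semi))
            assert equivalent_radius(e) <= maximum_radius(e) + 1e-15


class TestCoordinateGrain:
    def test_million_colors_imply_percent_grain(self):
        assert np.isclose(coordinate_grain(1e6), 0.01)

    def test_positive_count_required(self):
        with pytest.raises(ValueError):
            coordinate_grain(0)


class TestIlluminantVariation:
    def test_single_illuminant_gives_zero_volumes(self, grid, d65, rgb):
        objs = generate_reflectance(ReflectanceModel.default(grid), 5, seed=1)
        summary = illuminant_variation_grain(objs, [d65, d65, d65], rgb)
        assert all(e.volume == 0.0 for e in summary.ellipsoids)

    def test_white_object_is_invariant(self, grid, rgb):
        from colorgrain import fixtures as fx

        white = ReflectanceSpectrum(grid, np.ones(len(grid)))
        ills = fx.synthetic_daylight_database(grid, n=10, seed=3)
        summary = illuminant_variation_grain([white], ills, rgb)
        assert summary.ellipsoids[0].volume < 1e-30
        assert maximum_radius(summary.ellipsoids[0]) < 1e-9

    def test_n_marks_is_reciprocal_mean_volume(self, grid, rgb):
        from colorgrain import fixtures as fx

        objs = fx.synthetic_vegetation_database(grid, n=10, seed=4)
        ills = fx.synthetic_daylight_database(grid, n=10, seed=5)
        summary = illuminant_variation_grain(objs, ills, rgb)
        assert np.isclose(summary.n_marks * summary.mean_volume, 1.0)
        q = summary.equivalent_radius_quartiles
        assert q[0] <= q[1] <= q[2]


class TestMetamerismGrain:
    def test_degenerate_models_collapse_to_the_fiducial(self, grid, rgb, basis):
        base = DaylightModel.default(grid)
        frozen_day = DaylightModel(grid, base.mean_log, base.pc_basis,
                                   np.zeros((2, 2)), 4.0, 0.0)
        frozen_refl = ReflectanceModel(grid, articulation_amplitude=0.0)
        with pytest.raises(ValueError):
            # zero-amplitude blacks are identically zero -> no valid black
            metamerism_grain([ObjectColor(0.5, 0.5, 0.5)], 5, frozen_refl,
                             frozen_day, rgb, basis, seed=1)

    def test_frozen_daylight_and_scaled_blacks_stay_centered(self, grid, rgb, basis):
        base = DaylightModel.default(grid)
        frozen_day = DaylightModel(grid, base.mean_log, base.pc_basis,
                                   np.zeros((2, 2)), 4.0, 0.0)
        summary = metamerism_grain(
            [ObjectColor(0.5, 0.5, 0.5)], 20, ReflectanceModel.default(grid),
            frozen_day, rgb, basis, seed=2,
        )
        e = summary.ellipsoids[0]
        # under the standard illuminant all metamers collapse to one color
        assert np.abs(e.center - 0.5).max() < 1e-8
        assert e.volume < 1e-30

    def test_metamerism_exceeds_illuminant_only_grain(self, grid, rgb, basis):
        from colorgrain import fixtures as fx

        refl = ReflectanceModel.default(grid)
        day = DaylightModel.default(grid)
        fids = [ObjectColor(*v) for v in
                np.random.default_rng(3).uniform(0.25, 0.75, (8, 3))]
        meta = metamerism_grain(fids, 60, refl, day, rgb, basis, seed=4)
        objs = [ReflectanceSpectrum(grid, F.values) for F in
                (fx.synthetic_vegetation_database(grid, n=20, seed=5))]
        ills = fx.synthetic_daylight_database(grid, n=30, seed=6)
        ill_only = illuminant_variation_grain(objs, ills, rgb)
        assert meta.mean_volume > ill_only.mean_volume

    def test_boundary_fiducials_are_skipped(self, grid, rgb, basis):
        with pytest.warns(UserWarning, match="boundary"):
            with pytest.raises(ValueError):
                metamerism_grain([ObjectColor(1.0, 0.5, 0.5)], 5,
                                 ReflectanceModel.default(grid),
                                 DaylightModel.default(grid), rgb, basis, seed=7)


class TestGrainField:
    def test_lattice_arithmetic(self):
        assert len(interior_lattice(0.5)) == 1
        assert len(interior_lattice(0.25)) == 27
        with pytest.raises(ValueError):
            interior_lattice(1.0)

    def test_field_summary_is_ordered_and_positive(self, grid, rgb, basis):
        summary = grain_field(0.5, 40, ReflectanceModel.default(grid),
                              DaylightModel.default(grid), rgb, basis, seed=8)
        assert len(summary.ellipsoids) == 1
        q = summary.maximum_radius_quartiles
        assert 0 <= q[0] <= q[1] <= q[2]
        assert summary.mean_volume > 0

    def test_volumes_shrink_toward_the_faces(self, grid, rgb, basis):
        refl = ReflectanceModel.default(grid)
        day = DaylightModel.default(grid)
        center = metamerism_grain([ObjectColor(0.5, 0.5, 0.5)], 80, refl, day,
                                  rgb, basis, seed=9)
        near_face = metamerism_grain([ObjectColor(0.5, 0.5, 0.05)], 80, refl, day,
                                     rgb, basis, seed=9)
        assert near_face.mean_volume < center.mean_volume
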
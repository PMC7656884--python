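"""Color solid geometry: optimal spectra, crate search, canonical basis."""

import itertools

import numpy as np
import pytest

from colorgrain.solid import (
    Tripartition,
    band_occupancy,
    canonical_basis,
    canonical_spectrum,
    cardinal_colors,
    crate_volume,
    find_largest_crate,
    optimal_spectrum,
    part_matrix,
    rgb_cmfs,
    solid_boundary,
    solid_volume,
    _CumulativeTristimulus,
)
from colorgrain.spectra import (
    Cmfs,
    ObjectColor,
    Spectrum,
    cell_weights,
    object_color,
    tristimulus,
)


class TestOptimalSpectrum:
    def test_full_range_band_is_all_ones(self, grid):
        s = optimal_spectrum("band", 380, 720, grid)
        assert np.all(s.chi == 1)
        assert s.transitions == 0

    def test_empty_band_is_all_zeros(self, grid):
        s = optimal_spectrum("band", 500, 500, grid)
        assert np.all(s.chi == 0)

    def test_green_part_indicator(self, grid):
        s = optimal_spectrum("band", 482.65, 565.433, grid)
        assert s.transitions == 2
        wl = grid.wavelengths
        assert np.all(s.chi[(wl >= 483) & (wl < 565)] == 1)
        assert np.all(s.chi[wl < 482] == 0)
        assert np.all(s.chi[wl > 566] == 0)

    def test_band_stop_is_complement(self, grid):
        band = optimal_spectrum("band", 450, 600, grid)
        stop = optimal_spectrum("band_stop", 450, 600, grid)
        assert np.all(band.chi + stop.chi == 1)
        assert stop.transitions == 2

    def test_cuts_outside_grid_rejected(self, grid):
        with pytest.raises(ValueError):
            optimal_spectrum("band", 300, 500, grid)


class TestSolidBoundary:
    def test_contains_black_and_white(self, grid, d65, cmfs):
        mesh = solid_boundary(d65, cmfs, n=2)
        white = tristimulus(d65, cmfs).c
        assert np.any(np.all(np.isclose(mesh.points, 0.0, atol=1e-9), axis=1))
        assert np.any(np.all(np.isclose(mesh.points, white, rtol=1e-9), axis=1))

    def test_nested_refinement_keeps_points_inside_hull(self, grid, d65, cmfs):
        coarse = solid_boundary(d65, cmfs, n=61)
        fine = solid_boundary(d65, cmfs, n=121)  # cut lattice nests 61 -> 121
        eq = fine.hull.equations
        signed = coarse.points @ eq[:, :3].T + eq[:, 3]
        white = np.linalg.norm(tristimulus(d65, cmfs).c)
        assert signed.max() <= 1e-9 * white

    def test_hull_volume_converges(self, grid, d65, cmfs):
        v60 = solid_volume(d65, cmfs, 60)
        v120 = solid_volume(d65, cmfs, 120)
        assert abs(v120 - v60) / v120 < 0.01

    def test_single_sample_illuminant_is_degenerate(self, grid, cmfs):
        v = np.zeros(len(grid))
        v[170] = 1.0
        with pytest.raises(ValueError, match="degenerate"):
            solid_volume(Spectrum(grid, v), cmfs, 20)


class TestCrate:
    def test_near_degenerate_tripartition_has_tiny_volume(self, grid, d65, cmfs):
        t = Tripartition(500.0, 500.0 + 1e-9, grid)
        full = crate_volume(d65, cmfs, find_largest_crate(d65, cmfs))
        assert crate_volume(d65, cmfs, t) < 1e-9 * full

    def test_volume_invariant_under_part_permutation(self, grid, d65, cmfs, tripartition):
        M = part_matrix(d65, cmfs, tripartition)
        base = abs(np.linalg.det(M))
        for perm in itertools.permutations(range(3)):
            assert np.isclose(abs(np.linalg.det(M[:, perm])), base, rtol=1e-12)

    def test_search_beats_random_tripartitions(self, grid, d65, cmfs, tripartition, rng):
        best = crate_volume(d65, cmfs, tripartition)
        for _ in range(200):
            l1, l2 = np.sort(rng.uniform(381, 719, 2))
            if l2 - l1 < 1e-6:
                continue
            assert crate_volume(d65, cmfs, Tripartition(l1, l2, grid)) <= best * (
                1 + 1e-12
            )

    def test_equal_energy_optimum_matches_brute_force_oracle(self, grid):
        from colorgrain import fixtures as fx

        cmfs = fx.cie1931_cmfs(grid)
        ee = Spectrum(grid, np.ones(len(grid)))
        t = find_largest_crate(ee, cmfs)
        # independent oracle: dense lattice scan of the cumulative integrals
        cum = _CumulativeTristimulus(ee, cmfs)
        cuts = np.arange(380.2, 720.0, 0.2)
        C = cum.cumulative(cuts)
        i, j = np.triu_indices(len(cuts), 1)
        M = np.stack(
            [C[i], C[j] - C[i], np.broadcast_to(cum.total, C[i].shape) - C[j]], axis=2
        )
        k = np.abs(np.linalg.det(M)).argmax()
        assert abs(t.lambda1 - cuts[i[k]]) <= 0.2
        assert abs(t.lambda2 - cuts[j[k]]) <= 0.2

    def test_volume_ratio_is_basis_invariant(self, grid, d65, cmfs, tripartition, rng):
        ratio = crate_volume(d65, cmfs, tripartition) / solid_volume(d65, cmfs, 40)
        T = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        recmfs = Cmfs(grid, cmfs.values @ T.T, basis="xyz")
        ratio2 = crate_volume(d65, recmfs, tripartition) / solid_volume(d65, recmfs, 40)
        assert abs(ratio - ratio2) < 1e-9


class TestCanonicalBasis:
    def test_parts_partition_the_illuminant_exactly(self, grid, d65, basis):
        total = sum(p.values for p in basis.parts)
        assert np.abs(total - d65.values).max() <= 1e-13 * d65.values.max()

    def test_part_colors_are_rgb_unit_vectors(self, basis, rgb):
        expect = np.eye(3)[::-1]  # parts ordered blue, green, red
        for p, e in zip(basis.parts, expect):
            assert np.abs(tristimulus(p, rgb).c - e).max() < 1e-12

    def test_supplementary_pairs_add_to_white(self, grid, basis, cmfs):
        blue, green, red = basis.parts
        yellow_union = Spectrum(grid, green.values + red.values)
        lhs = tristimulus(yellow_union, cmfs).c + tristimulus(blue, cmfs).c
        white = tristimulus(basis.illuminant, cmfs).c
        assert np.allclose(lhs, white, rtol=1e-12)


class TestCanonicalSpectrum:
    @pytest.mark.parametrize(
        "c", [(1, 1, 1), (0, 0, 0), (0.156, 0.057, 0.016), (0.5, 0.5, 0.5)]
    )
    def test_round_trip_recovers_the_color(self, grid, d65, basis, rgb, c):
        F = canonical_spectrum(ObjectColor(*c), basis)
        back = np.array(object_color(F, d65, rgb))
        assert np.abs(back - np.array(c)).max() < 1e-9

    def test_white_and_black_levels(self, grid, basis):
        assert np.all(canonical_spectrum(ObjectColor(1, 1, 1), basis).values == 1.0)
        assert np.all(canonical_spectrum(ObjectColor(0, 0, 0), basis).values == 0.0)

    def test_three_level_structure(self, grid, basis):
        F = canonical_spectrum(ObjectColor(0.156, 0.057, 0.016), basis)
        interior = np.unique(F.values[2:-2])
        # at most 3 plateau levels plus the fractional cut cells
        assert len(interior) <= 5
        for level in (0.156, 0.057, 0.016):
            assert np.isclose(interior, level, atol=1e-12).any()

    def test_out_of_cube_rejected(self, basis):
        with pytest.raises(ValueError):
            canonical_spectrum(ObjectColor(1.2, 0.5, 0.5), basis)


class TestCardinalColors:
    def test_black_white_and_supplementarity(self, basis):
        cc = cardinal_colors(basis)
        assert cc["k"] == (0, 0, 0) and cc["w"] == (1, 1, 1)
        for a, b in (("r", "c"), ("g", "m"), ("b", "y")):
            assert np.allclose(
                np.array(cc[a]) + np.array(cc[b]), (1, 1, 1)
            )

    def test_vertices_lie_on_the_solid_boundary(self, grid, d65, cmfs, basis):
        mesh = solid_boundary(d65, cmfs, 100)
        eq = mesh.hull.equations
        white = np.linalg.norm(tristimulus(d65, cmfs).c)
        for v in cardinal_colors(basis).values():
            x = basis.matrix @ np.array(v)
            signed = (eq[:, :3] @ x + eq[:, 3]).max()
            assert abs(signed) < 1e-3 * white


class TestSchroedingerProperty:
    def test_hull_vertices_of_coarse_binary_colors_have_two_transitions(
        self, grid, d65, cmfs
    ):
        from scipy.spatial import ConvexHull

        y = (d65.values * cell_weights(grid))[:, None] * cmfs.values
        edges = np.linspace(0, len(grid), 13).astype(int)
        bands = np.array([y[a:b].sum(axis=0) for a, b in zip(edges[:-1], edges[1:])])
        patterns = np.array(list(itertools.product([0, 1], repeat=12)))
        hull = ConvexHull(patterns @ bands)
        transitions = (np.diff(patterns[hull.vertices]) != 0).sum(axis=1)
        assert transitions.max() <= 2
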
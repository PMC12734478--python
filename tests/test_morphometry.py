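"""Porosity profiles and Euclidean-distance-map pore sizing.

The distance-map oracle is an exhaustive nearest-solid search over all
voxel pairs, independent of the scipy transform used by the
implementation.
"""

import numpy as np
import pytest

from poreflow import VoxelStructure, pore_size_distribution, porosity_profile


def brute_force_distances(grid: np.ndarray) -> np.ndarray:
    """Exhaustive nearest-solid distance (voxel units) for each pore voxel."""
    pores = np.argwhere(grid)
    solids = np.argwhere(~grid)
    diff = pores[:, None, :] - solids[None, :, :]
    return np.sqrt((diff**2).sum(axis=2)).min(axis=1)


class TestPorosityProfile:
    def test_all_pore_structure_is_unit_porosity(self):
        s = VoxelStructure(np.ones((8, 8, 80), bool))
        prof = porosity_profile(s)
        assert np.allclose(prof.porosity, 1.0)

    def test_checkerboard_is_half(self):
        idx = np.indices((8, 8, 80)).sum(axis=0)
        s = VoxelStructure(idx % 2 == 0)
        prof = porosity_profile(s)
        assert np.allclose(prof.porosity, 0.5)

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(7)
        s = VoxelStructure(rng.random((12, 12, 100)) < 0.4)
        prof = porosity_profile(s, slab_nm=250.0)
        per_slab = round(250.0 / 7.0)  # 36 slices
        for i, (z0) in enumerate(range(0, 100, per_slab)):
            z1 = min(z0 + per_slab, 100)
            expect = s.grid[:, :, z0:z1].mean()
            assert prof.porosity[i] == pytest.approx(expect)

    def test_midpoints_and_partial_final_slab(self):
        s = VoxelStructure(np.ones((4, 4, 50), bool))
        prof = porosity_profile(s, slab_nm=250.0)  # 36 + 14 slices
        assert prof.slab_thickness_nm[-1] == pytest.approx(14 * 7.0)
        assert prof.midpoints_um[0] == pytest.approx(0.5 * 36 * 7e-3)

    def test_slab_below_voxel_size_rejected(self):
        s = VoxelStructure(np.ones((4, 4, 8), bool))
        with pytest.raises(ValueError):
            porosity_profile(s, slab_nm=3.0)

    def test_valid_mask_excludes_voxels(self):
        grid = np.ones((4, 4, 8), bool)
        grid[0] = False
        valid = np.zeros_like(grid)
        valid[0] = True  # only count the solid block
        prof = porosity_profile(VoxelStructure(grid), slab_nm=56.0, valid=valid)
        assert np.allclose(prof.porosity, 0.0)


class TestPoreSizeDistribution:
    def test_single_pore_voxel_is_two_voxels_wide(self):
        grid = np.zeros((5, 5, 5), bool)
        grid[2, 2, 2] = True
        psd = pore_size_distribution(VoxelStructure(grid, voxel_size_nm=7.0))
        assert psd.diameters_nm.tolist() == [14.0]

    def test_planar_slab_maximum_diameter(self):
        # 7-voxel pore slab between solid half-spaces: centre voxel is 4
        # voxel units from the nearest solid centre -> diameter 56 nm
        grid = np.zeros((16, 16, 9), bool)
        grid[:, :, 1:8] = True
        psd = pore_size_distribution(VoxelStructure(grid, voxel_size_nm=7.0))
        assert psd.diameters_nm.max() == pytest.approx(56.0)

    def test_counts_conserve_pore_voxels(self):
        rng = np.random.default_rng(3)
        s = VoxelStructure(rng.random((10, 10, 30)) < 0.5)
        psd = pore_size_distribution(s, region=(5, 20))
        assert psd.counts.sum() == s.grid[:, :, 5:20].sum()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_match_with_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        grid = rng.random((12, 12, 12)) < 0.5
        if not grid.any() or grid.all():
            pytest.skip("degenerate draw")
        s = VoxelStructure(grid)
        psd = pore_size_distribution(s)
        expect = np.sort(2.0 * brute_force_distances(grid) * 7.0)
        assert np.allclose(np.sort(psd.diameters_nm), expect)

    def test_distances_are_non_integer_on_angled_pore(self):
        # exact Euclidean metric: a pore voxel whose nearest solid is a
        # diagonal neighbour sits sqrt(2) away, so voxel-multiple
        # diameters are a discretization artifact of the structure, not
        # of the metric (no chamfer rounding)
        grid = np.zeros((7, 7, 7), bool)
        grid[3, 3, 3] = True  # centre of a 3D cross: face neighbours pore
        grid[2, 3, 3] = grid[4, 3, 3] = True
        grid[3, 2, 3] = grid[3, 4, 3] = True
        grid[3, 3, 2] = grid[3, 3, 4] = True
        psd = pore_size_distribution(VoxelStructure(grid, voxel_size_nm=7.0))
        ratios = psd.diameters_nm / 14.0  # distance in voxel units
        assert not np.allclose(ratios, np.round(ratios))
        assert np.isclose(ratios, np.sqrt(2.0)).any()

    def test_no_solid_is_an_error(self):
        s = VoxelStructure(np.ones((4, 4, 4), bool))
        with pytest.raises(ValueError, match="no solid"):
            pore_size_distribution(s)


class TestFoulingEffectOnPSD:
    def test_size_survival_counts_never_increase_under_fouling(self, membrane_small):
        """Deposition only removes pore voxels and shrinks survivors'
        diameters, so the count of voxels at or above any diameter is
        pointwise non-increasing (the distributional direction of
        fouling).  Note population quantiles can rise when small pores
        are removed preferentially, so counts are the right statistic."""
        from poreflow import FoulingSpec, apply_fouling

        fouled = apply_fouling(membrane_small, FoulingSpec(deposit_fraction=0.4), seed=9)
        before = pore_size_distribution(membrane_small).diameters_nm
        after = pore_size_distribution(fouled).diameters_nm
        for x in np.arange(7.0, before.max() + 7.0, 7.0):
            assert (after >= x).sum() <= (before >= x).sum()
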
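"""Volumetric data model, I/O round trips, and preprocessing operators."""

import nibabel as nib
import numpy as np
import pytest

from tremornet import errors
from tremornet.volumes import (
    BrainMap,
    VolumeGrid,
    gaussian_smooth,
    intensity_normalize,
    mirror,
    read_volume,
    resample,
    write_volume,
)


@pytest.fixture()
def grid():
    return VolumeGrid.centered((8, 8, 8), 2.0)


class TestGridAndIO:
    def test_world_coordinates_are_origin_plus_index_times_voxel(self):
        g = VolumeGrid((3, 3, 3), (2.0, 3.0, 4.0), (-2.0, 0.0, 1.0))
        c = g.world_coords().reshape(3, 3, 3, 3)
        assert np.allclose(c[0, 0, 0], [-2.0, 0.0, 1.0])
        assert np.allclose(c[2, 1, 0], [-2.0 + 4.0, 3.0, 1.0])

    def test_round_trip_preserves_values_grid_and_mask(self, grid, rng, tmp_path):
        data = rng.normal(size=grid.shape)
        mask = rng.random(grid.shape) > 0.3
        mask[:2] = True  # ensure >= 2 voxels
        bmap = BrainMap(grid, data, mask)
        write_volume(bmap, tmp_path / "m.nii.gz")
        back = read_volume(tmp_path / "m.nii.gz", mask=mask)
        assert back.grid == grid
        np.testing.assert_allclose(back.values, bmap.values, rtol=1e-6)
        assert np.array_equal(back.mask, mask)

    def test_nonzero_mask_excludes_nan_and_zero_voxels(self, grid, tmp_path):
        data = np.ones(grid.shape, dtype=np.float32)
        data[0, 0, 0] = np.nan
        data[1, 1, 1] = 0.0
        nib.save(nib.Nifti1Image(data, grid.affine), tmp_path / "x.nii.gz")
        bmap = read_volume(tmp_path / "x.nii.gz", mask="nonzero")
        assert not bmap.mask[0, 0, 0]
        assert not bmap.mask[1, 1, 1]
        assert bmap.mask.sum() == np.prod(grid.shape) - 2

    def test_four_dimensional_file_rejected(self, tmp_path):
        nib.save(
            nib.Nifti1Image(np.zeros((4, 4, 4, 2), dtype=np.float32), np.eye(4)),
            tmp_path / "f4.nii.gz",
        )
        with pytest.raises(errors.DimensionalityError):
            read_volume(tmp_path / "f4.nii.gz")

    def test_rotated_affine_rejected(self, tmp_path):
        aff = np.eye(4)
        aff[0, 1] = 0.5  # shear
        nib.save(nib.Nifti1Image(np.zeros((4, 4, 4), dtype=np.float32), aff),
                 tmp_path / "rot.nii.gz")
        with pytest.raises(errors.UnsupportedOrientationError):
            read_volume(tmp_path / "rot.nii.gz")


class TestIntensityNormalize:
    def test_constant_map_becomes_one_everywhere(self, grid):
        bmap = BrainMap(grid, np.full(grid.shape, 7.5))
        ref = np.zeros(grid.shape, dtype=bool)
        ref[2:4, 2:4, 2:4] = True
        out = intensity_normalize(bmap, ref)
        assert np.allclose(out.values, 1.0)

    def test_two_voxel_reference_mean(self, grid):
        data = np.ones(grid.shape)
        data[0, 0, 0], data[0, 0, 1] = 1.0, 3.0
        ref = np.zeros(grid.shape, dtype=bool)
        ref[0, 0, 0] = ref[0, 0, 1] = True
        out = intensity_normalize(BrainMap(grid, data), ref)
        assert out.data[0, 0, 0] == pytest.approx(0.5)
        assert out.data[0, 0, 1] == pytest.approx(1.5)

    def test_reference_mean_is_one_after_normalization_and_idempotent(self, grid, rng):
        bmap = BrainMap(grid, rng.lognormal(size=grid.shape))
        ref = rng.random(grid.shape) > 0.5
        out = intensity_normalize(bmap, ref)
        assert out.data[ref].mean() == pytest.approx(1.0, abs=1e-12)
        again = intensity_normalize(out, ref)
        np.testing.assert_allclose(again.data, out.data, atol=1e-14)

    def test_zero_reference_mean_rejected(self, grid):
        data = np.zeros(grid.shape)
        data[4, 4, 4] = 1.0
        ref = np.zeros(grid.shape, dtype=bool)
        ref[0, 0, 0] = ref[0, 0, 1] = True
        with pytest.raises(errors.DegenerateNormalizationError):
            intensity_normalize(BrainMap(grid, data), ref)


class TestGaussianSmooth:
    def test_zero_fwhm_is_identity(self, grid, rng):
        bmap = BrainMap(grid, rng.normal(size=grid.shape))
        out = gaussian_smooth(bmap, 0.0)
        np.testing.assert_array_equal(out.data, bmap.data)

    def test_unit_impulse_kernel_is_normalized_and_peaked(self, grid):
        data = np.zeros(grid.shape)
        data[4, 4, 4] = 1.0
        out = gaussian_smooth(BrainMap(grid, data), 4.0)
        assert out.data.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.unravel_index(np.argmax(out.data), grid.shape) == (4, 4, 4)

    def test_constant_map_unchanged_in_interior(self, grid):
        # wide all-true mask, small kernel: interior voxels stay constant
        out = gaussian_smooth(BrainMap(grid, np.full(grid.shape, 3.0)), 2.0)
        assert out.data[3:5, 3:5, 3:5] == pytest.approx(3.0, abs=1e-6)

    def test_global_sum_preserved_for_interior_signal(self, grid, rng):
        data = np.zeros(grid.shape)
        data[3:5, 3:5, 3:5] = rng.random((2, 2, 2))
        out = gaussian_smooth(BrainMap(grid, data), 3.0)
        assert out.data.sum() == pytest.approx(data.sum(), rel=1e-6)


class TestResample:
    def test_constant_map_stays_constant(self, grid):
        out = resample(BrainMap(grid, np.full(grid.shape, 2.5)), 4.0)
        assert out.grid.shape == (4, 4, 4)
        assert out.grid.voxel_size_mm == (4.0, 4.0, 4.0)
        assert np.allclose(out.values, 2.5)

    def test_block_mean_value(self, grid):
        data = np.zeros(grid.shape)
        data[0:2, 0:2, 0:1] = 0.0
        data[0:2, 0:2, 1:2] = 8.0
        out = resample(BrainMap(grid, data), 4.0)
        assert out.data[0, 0, 0] == pytest.approx(4.0)

    def test_majority_rule_masks_out_sparse_blocks(self, grid):
        mask = np.zeros(grid.shape, dtype=bool)
        mask[0, 0, 0:3] = True      # 3 of 8 voxels of the first block
        mask[4:, 4:, 4:] = True     # keep a valid region elsewhere
        out = resample(BrainMap(grid, np.ones(grid.shape), mask), 4.0)
        assert not out.mask[0, 0, 0]
        assert out.mask[2:, 2:, 2:].all()

    def test_non_integer_ratio_rejected(self, grid):
        with pytest.raises(errors.UnsupportedResamplingError):
            resample(BrainMap(grid, np.ones(grid.shape)), 3.0)

    def test_block_mean_preserves_masked_mean(self, grid, rng):
        bmap = BrainMap(grid, rng.normal(size=grid.shape))
        out = resample(bmap, 4.0)
        # all blocks fully in-mask: coarse mean equals fine mean
        assert out.values.mean() == pytest.approx(bmap.values.mean(), abs=1e-12)


class TestMirror:
    def make_left_map(self, grid):
        xcoords = grid.axis_coords(0)
        mask = np.zeros(grid.shape, dtype=bool)
        mask[xcoords < 0] = True
        data = np.where(mask, np.arange(np.prod(grid.shape)).reshape(grid.shape) + 1.0, 0.0)
        return BrainMap(grid, data, mask)

    def test_symmetric_map_is_fixed_point_of_bilateral(self, grid, rng):
        half = rng.normal(size=(4, 8, 8))
        data = np.concatenate([half, half[::-1]], axis=0)
        bmap = BrainMap(grid, data)
        out = mirror(bmap, "left_to_right_bilateral")
        np.testing.assert_allclose(out.data, bmap.data)

    def test_average_to_left_averages_pairs(self, grid):
        data = np.zeros(grid.shape)
        data[0, 4, 4] = 2.0          # x = -7 mm
        data[7, 4, 4] = 6.0          # x = +7 mm (reflection partner)
        out = mirror(BrainMap(grid, data), "average_to_left")
        assert out.data[0, 4, 4] == pytest.approx(4.0)
        assert not out.mask[7, 4, 4]

    def test_bilateral_then_average_recovers_left_map(self, grid):
        left = self.make_left_map(grid)
        bilateral = mirror(left, "left_to_right_bilateral")
        back = mirror(bilateral, "average_to_left")
        np.testing.assert_allclose(back.data[left.mask], left.data[left.mask])
        assert np.array_equal(back.mask, left.mask)

    def test_grid_not_reflectable_rejected(self):
        g = VolumeGrid((8, 8, 8), (2.0, 2.0, 2.0), origin_mm=(-7.5, -7.0, -7.0))
        with pytest.raises(errors.AsymmetricGridError):
            mirror(BrainMap(g, np.ones(g.shape)), "left_to_right_bilateral")
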
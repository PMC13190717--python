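"""Volumetric data model, NIfTI I/O, and per-map preprocessing operators.

A :class:`BrainMap` is a real-valued 3-D volume restricted to an analysis
mask on an axis-aligned :class:`VolumeGrid`. The operators here are the ones
applied to every map entering the pipeline: intensity normalization to a
reference (parenchyma) region, Gaussian smoothing specified in mm FWHM,
integer-block down-sampling, and hemisphere mirroring about the midsagittal
plane x = 0.

Only axis-aligned geometry is supported: the world coordinate of voxel
``(i, j, k)`` is ``origin + index * voxel_size``. Volumes whose affine
carries rotation or shear are rejected at read time rather than silently
resampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import (
    AsymmetricGridError,
    DegenerateNormalizationError,
    DimensionalityError,
    GridMismatchError,
    UnsupportedOrientationError,
    UnsupportedResamplingError,
)

#: Conversion factor between full width at half maximum and Gaussian sigma.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class VolumeGrid:
    """Axis-aligned voxel grid geometry.

    Parameters
    ----------
    shape
        Number of voxels per axis ``(nx, ny, nz)``.
    voxel_size_mm
        Positive voxel edge length per axis in mm.
    origin_mm
        World coordinate (mm) of the center of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise DimensionalityError(f"grid shape must be a positive triple, got {self.shape}")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size_mm}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm))
        object.__setattr__(self, "origin_mm", tuple(float(v) for v in self.origin_mm))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world affine (diagonal by construction)."""
        aff = np.eye(4)
        aff[[0, 1, 2], [0, 1, 2]] = self.voxel_size_mm
        aff[:3, 3] = self.origin_mm
        return aff

    def axis_coords(self, axis: int) -> np.ndarray:
        """World-mm coordinates of voxel centers along one axis."""
        return self.origin_mm[axis] + np.arange(self.shape[axis]) * self.voxel_size_mm[axis]

    def world_coords(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(N, 3) world-mm coordinates of all (or in-mask) voxel centers."""
        idx = (
            np.indices(self.shape).reshape(3, -1).T
            if mask is None
            else np.argwhere(np.asarray(mask, dtype=bool))
        )
        return np.asarray(self.origin_mm) + idx * np.asarray(self.voxel_size_mm)

    @classmethod
    def centered(
        cls,
        shape: tuple[int, int, int],
        voxel_size_mm: float | tuple[float, float, float],
    ) -> "VolumeGrid":
        """Grid whose voxel centers straddle world 0 symmetrically per axis.

        With an even number of voxels no center falls exactly on 0, which
        makes the x = 0 midsagittal reflection an exact voxel-to-voxel map.
        """
        if np.isscalar(voxel_size_mm):
            voxel_size_mm = (float(voxel_size_mm),) * 3
        origin = tuple(-(s - 1) / 2.0 * v for s, v in zip(shape, voxel_size_mm))
        return cls(tuple(shape), tuple(voxel_size_mm), origin)


class BrainMap:
    """Real-valued volume restricted to an analysis mask.

    ``data`` is stored on the full grid with out-of-mask voxels fixed at 0;
    ``values`` exposes the in-mask vector used by all statistics.
    """

    def __init__(self, grid: VolumeGrid, data: np.ndarray, mask: np.ndarray | None = None):
        data = np.asarray(data, dtype=float)
        if data.shape != grid.shape:
            raise GridMismatchError(f"data shape {data.shape} != grid shape {grid.shape}")
        if mask is None:
            mask = np.ones(grid.shape, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != grid.shape:
            raise GridMismatchError(f"mask shape {mask.shape} != grid shape {grid.shape}")
        if mask.sum() < 2:
            raise ValueError("mask must contain at least 2 voxels")
        if not np.all(np.isfinite(data[mask])):
            raise ValueError("in-mask values must all be finite")
        self.grid = grid
        self.mask = mask
        self.data = np.where(mask, data, 0.0)

    # -- basic accessors -------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        """In-mask values as a 1-D vector (C-order of in-mask voxels)."""
        return self.data[self.mask]

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def with_values(self, values: np.ndarray) -> "BrainMap":
        """New map on the same grid/mask with replaced in-mask values."""
        data = np.zeros(self.grid.shape)
        data[self.mask] = np.asarray(values, dtype=float)
        return BrainMap(self.grid, data, self.mask)

    def same_geometry(self, other: "BrainMap") -> bool:
        return self.grid == other.grid and np.array_equal(self.mask, other.mask)

    def require_same_grid(self, other: "BrainMap", what: str = "maps") -> None:
        if self.grid != other.grid:
            raise GridMismatchError(f"{what} are on different grids")

    # -- arithmetic used throughout the pipeline -------------------------
    def __sub__(self, other: "BrainMap") -> "BrainMap":
        self.require_same_grid(other)
        return BrainMap(self.grid, self.data - other.data, self.mask & other.mask)

    def __add__(self, other: "BrainMap") -> "BrainMap":
        self.require_same_grid(other)
        return BrainMap(self.grid, self.data + other.data, self.mask & other.mask)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _grid_from_affine(affine: np.ndarray, shape: tuple[int, ...]) -> VolumeGrid:
    lin = affine[:3, :3]
    diag = np.diag(lin)
    off = lin - np.diag(diag)
    if np.max(np.abs(off)) > 1e-6 * max(1.0, np.max(np.abs(diag))):
        raise UnsupportedOrientationError(
            "volume affine carries rotation/shear; only axis-aligned grids are supported"
        )
    if np.any(diag <= 0):
        raise UnsupportedOrientationError(
            "volume affine has non-positive scales (flipped axes); "
            "reorient to a positive axis-aligned affine first"
        )
    return VolumeGrid(tuple(int(s) for s in shape), tuple(diag), tuple(affine[:3, 3]))


def read_volume(path, mask: np.ndarray | str | None = "nonzero") -> BrainMap:
    """Read a NIfTI volume as a :class:`BrainMap`.

    Parameters
    ----------
    path
        A ``.nii``/``.nii.gz`` file with a 3-D, axis-aligned image.
    mask
        ``"nonzero"`` (default) masks to nonzero finite voxels; ``None``
        masks the full grid (non-finite voxels rejected); an explicit
        boolean array is used as-is.
    """
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise DimensionalityError(f"expected a 3-D volume, got shape {img.shape}")
    grid = _grid_from_affine(img.affine, img.shape)
    data = np.asarray(img.get_fdata(), dtype=float)
    if isinstance(mask, str):
        if mask != "nonzero":
            raise ValueError(f"unknown mask mode {mask!r}")
        mask = np.isfinite(data) & (data != 0)
    elif mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    data = np.where(np.isfinite(data), data, 0.0)
    return BrainMap(grid, data, mask)


def write_volume(bmap: BrainMap, path) -> None:
    """Write a map as float32 NIfTI (out-of-mask voxels stored as 0)."""
    img = nib.Nifti1Image(bmap.data.astype(np.float32), bmap.grid.affine)
    nib.save(img, str(path))


def write_mask(mask: np.ndarray, grid: VolumeGrid, path) -> None:
    """Write a boolean mask as uint8 NIfTI."""
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), grid.affine)
    nib.save(img, str(path))


def read_mask(path) -> tuple[np.ndarray, VolumeGrid]:
    bmap = read_volume(path, mask=None)
    return bmap.data > 0.5, bmap.grid


# ---------------------------------------------------------------------------
# Preprocessing operators
# ---------------------------------------------------------------------------

def intensity_normalize(bmap: BrainMap, reference_mask: np.ndarray) -> BrainMap:
    """Divide by the mean over a reference (parenchyma) region.

    After normalization the mean over ``reference_mask`` is exactly 1, so
    maps from different scans share a common global scale.
    """
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if reference_mask.shape != bmap.grid.shape:
        raise GridMismatchError("reference mask is on a different grid")
    if np.any(reference_mask & ~bmap.mask):
        raise GridMismatchError("reference mask extends outside the map mask")
    ref_mean = bmap.data[reference_mask].mean()
    if abs(ref_mean) < 1e-300:
        raise DegenerateNormalizationError("reference-region mean is zero")
    return BrainMap(bmap.grid, bmap.data / ref_mean, bmap.mask)


def gaussian_smooth(bmap: BrainMap, fwhm_mm: float) -> BrainMap:
    """Separable Gaussian smoothing with kernel width given in mm FWHM.

    Out-of-mask voxels enter the convolution as 0 (zero padding) and the
    result is re-masked; no mask-weighted renormalization is applied.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    if fwhm_mm == 0:
        return BrainMap(bmap.grid, bmap.data.copy(), bmap.mask)
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / v for v in bmap.grid.voxel_size_mm]
    smoothed = ndimage.gaussian_filter(bmap.data, sigma=sigma_vox, mode="constant", cval=0.0)
    return BrainMap(bmap.grid, smoothed, bmap.mask)


def resample(bmap: BrainMap, target_voxel_mm: float | tuple[float, float, float]) -> BrainMap:
    """Block-mean down-sampling to an integer multiple of the voxel size.

    Each output voxel is the mean of the *in-mask* source voxels in its
    block; the output voxel is in-mask iff at least half of its block is.
    """
    if np.isscalar(target_voxel_mm):
        target_voxel_mm = (float(target_voxel_mm),) * 3
    factors = []
    for axis in range(3):
        ratio = target_voxel_mm[axis] / bmap.grid.voxel_size_mm[axis]
        f = int(round(ratio))
        if f < 1 or abs(ratio - f) > 1e-6:
            raise UnsupportedResamplingError(
                f"target voxel {target_voxel_mm[axis]} mm is not an integer multiple "
                f"of source {bmap.grid.voxel_size_mm[axis]} mm on axis {axis}"
            )
        factors.append(f)
    # pad with out-of-mask zeros so every axis is divisible by its factor
    pad = [(0, (-bmap.grid.shape[a]) % factors[a]) for a in range(3)]
    data = np.pad(bmap.data, pad)
    mask = np.pad(bmap.mask, pad)
    new_shape = tuple(data.shape[a] // factors[a] for a in range(3))
    blocks = (
        new_shape[0], factors[0],
        new_shape[1], factors[1],
        new_shape[2], factors[2],
    )
    dat6 = data.reshape(blocks)
    msk6 = mask.reshape(blocks)
    counts = msk6.sum(axis=(1, 3, 5))
    sums = np.where(msk6, dat6, 0.0).sum(axis=(1, 3, 5))
    block_size = int(np.prod(factors))
    out_mask = counts * 2 >= block_size
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    out = np.where(out_mask, out, 0.0)
    # output origin = center of the first block
    origin = tuple(
        bmap.grid.origin_mm[a] + (factors[a] - 1) / 2.0 * bmap.grid.voxel_size_mm[a]
        for a in range(3)
    )
    new_grid = VolumeGrid(new_shape, tuple(target_voxel_mm), origin)
    if out_mask.sum() < 2:
        raise UnsupportedResamplingError("resampling left fewer than 2 in-mask voxels")
    return BrainMap(new_grid, out, out_mask)


def _reflection_partner_index(grid: VolumeGrid) -> np.ndarray:
    """Per x-index, the x-index whose world x-coordinate is the negation.

    Returns -1 where the reflected center falls outside the grid. Raises
    when the reflection does not map voxel centers onto voxel centers.
    """
    dx = grid.voxel_size_mm[0]
    # partner j of index i satisfies origin + j dx = -(origin + i dx)
    t = -2.0 * grid.origin_mm[0] / dx
    if abs(t - round(t)) > 1e-6:
        raise AsymmetricGridError(
            "grid is not symmetric about x = 0; reflection would fall between voxels"
        )
    partners = int(round(t)) - np.arange(grid.shape[0])
    partners[(partners < 0) | (partners >= grid.shape[0])] = -1
    if np.all(partners < 0):
        raise AsymmetricGridError("no voxel pair straddles the midsagittal plane x = 0")
    return partners


def mirror(bmap: BrainMap, mode: str) -> BrainMap:
    """Reflect about the midsagittal plane x = 0 (first axis = left-right).

    ``left_to_right_bilateral``
        Fill previously-empty voxels with their reflected partner's value,
        keeping existing values, yielding a bilateral map.
    ``average_to_left``
        For every left-hemisphere voxel (world x < 0), average the voxel
        with its reflected partner (mask-aware); the right hemisphere and
        the x = 0 plane are masked out.
    """
    partners = _reflection_partner_index(bmap.grid)
    have_partner = partners >= 0
    safe = np.where(have_partner, partners, 0)
    refl_data = bmap.data[safe]          # value at the reflected x index
    refl_mask = bmap.mask[safe] & have_partner[:, None, None]

    if mode == "left_to_right_bilateral":
        fill = ~bmap.mask & refl_mask
        data = np.where(fill, refl_data, bmap.data)
        mask = bmap.mask | fill
        return BrainMap(bmap.grid, data, mask)

    if mode == "average_to_left":
        xcoords = bmap.grid.axis_coords(0)
        left = (xcoords < 0)[:, None, None] & np.ones(bmap.grid.shape, dtype=bool)
        counts = bmap.mask.astype(int) + refl_mask.astype(int)
        sums = np.where(bmap.mask, bmap.data, 0.0) + np.where(refl_mask, refl_data, 0.0)
        mask = left & (counts > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            data = np.where(mask, sums / np.maximum(counts, 1), 0.0)
        if mask.sum() < 2:
            raise AsymmetricGridError("average_to_left left fewer than 2 in-mask voxels")
        return BrainMap(bmap.grid, data, mask)

    raise ValueError(f"unknown mirror mode {mode!r}")
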
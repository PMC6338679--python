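"""Data model and NIfTI I/O for volumes, grids, and voxel masks.

All geometric conventions used by the package live here. Volumes are kept on
an isotropic grid with fixed axis semantics:

* ``x`` runs left -> right,
* ``y`` runs posterior -> anterior,
* ``z`` runs caudal -> rostral (the brainstem long axis).

Voxel indices are 0-based and a voxel's physical center sits at
``index * voxel_size_mm`` along each axis. Images read from disk are
reoriented to the closest RAS-like layout before any index arithmetic, so the
semantics above hold regardless of how a file was stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "AXIS_SEMANTICS",
    "VolumeGrid",
    "ScalarVolume",
    "VoxelMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "mask_volume_mm3",
    "mask_extent_mm",
]

AXIS_SEMANTICS = {
    "x": "left->right",
    "y": "posterior->anterior",
    "z": "caudal->rostral",
}

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}

#: Default isotropic voxel size in mm of the analysis space.
DEFAULT_VOXEL_SIZE_MM = 0.8


@dataclass(frozen=True)
class VolumeGrid:
    """Geometry of a 3-D image: shape plus isotropic voxel size in mm."""

    shape: tuple[int, int, int]
    voxel_size_mm: float = DEFAULT_VOXEL_SIZE_MM

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be three entries >= 1, got {self.shape}")
        if not (self.voxel_size_mm > 0):
            raise ValueError(f"voxel_size_mm must be positive, got {self.voxel_size_mm}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size_mm", float(self.voxel_size_mm))

    @property
    def axis_semantics(self) -> dict[str, str]:
        return dict(AXIS_SEMANTICS)

    def affine(self) -> np.ndarray:
        """RAS-like affine with the voxel size on the diagonal."""
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff


@dataclass
class ScalarVolume:
    """A 3-D field of finite, non-negative intensities on a grid."""

    grid: VolumeGrid
    intensities: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.intensities, dtype=float)
        if data.shape != self.grid.shape:
            raise ValueError(
                f"intensity shape {data.shape} does not match grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("intensities must be finite (no NaN/Inf)")
        if np.any(data < 0):
            raise ValueError("intensities must be non-negative")
        self.intensities = data


@dataclass
class VoxelMask:
    """A labeled set of voxels on a grid, stored as a boolean field."""

    grid: VolumeGrid
    data: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {data.shape} does not match grid shape {self.grid.shape}"
            )
        self.data = data.astype(bool)

    @classmethod
    def from_indices(
        cls, grid: VolumeGrid, indices: np.ndarray, label: str = ""
    ) -> "VoxelMask":
        """Build a mask from an (N, 3) array of 0-based voxel index triples."""
        idx = np.atleast_2d(np.asarray(indices, dtype=int))
        data = np.zeros(grid.shape, dtype=bool)
        if idx.size:
            if idx.shape[1] != 3:
                raise ValueError("indices must be an (N, 3) array")
            if np.any(idx < 0) or np.any(idx >= np.array(grid.shape)):
                raise ValueError("mask indices fall outside the grid")
            data[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        return cls(grid=grid, data=data, label=label)

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    @property
    def indices(self) -> np.ndarray:
        """(N, 3) array of member voxel indices in C order."""
        return np.argwhere(self.data)

    def intersection(self, other: "VoxelMask", label: str = "") -> "VoxelMask":
        self._check_same_grid(other)
        return VoxelMask(self.grid, self.data & other.data, label=label)

    def union(self, other: "VoxelMask", label: str = "") -> "VoxelMask":
        self._check_same_grid(other)
        return VoxelMask(self.grid, self.data | other.data, label=label)

    def _check_same_grid(self, other: "VoxelMask") -> None:
        if other.grid.shape != self.grid.shape:
            raise ValueError(
                f"masks live on different grids: {self.grid.shape} vs {other.grid.shape}"
            )


def _grid_from_header(img: nib.Nifti1Image, *, iso_tolerance: float,
                      expected_voxel_size_mm: float | None) -> VolumeGrid:
    zooms = img.header.get_zooms()[:3]
    vmax, vmin = max(zooms), min(zooms)
    if vmax - vmin > iso_tolerance:
        raise ValueError(
            f"anisotropic voxels {tuple(round(z, 4) for z in zooms)} exceed the "
            f"{iso_tolerance} mm isotropy tolerance"
        )
    voxel_size = float(np.mean(zooms))
    if expected_voxel_size_mm is not None and abs(voxel_size - expected_voxel_size_mm) > iso_tolerance:
        raise ValueError(
            f"voxel size {voxel_size:g} mm does not match the required "
            f"{expected_voxel_size_mm:g} mm"
        )
    return VolumeGrid(shape=tuple(int(s) for s in img.shape[:3]), voxel_size_mm=voxel_size)


def read_volume(path, *, iso_tolerance: float = 1e-3,
                expected_voxel_size_mm: float | None = None) -> ScalarVolume:
    """Read a 3-D NIfTI-1 image as a :class:`ScalarVolume`.

    The image is reoriented to the closest canonical (RAS-like) axis layout so
    the package's axis semantics apply. 4-D or non-scalar images are rejected,
    as are voxel grids that are anisotropic beyond ``iso_tolerance`` or (when
    ``expected_voxel_size_mm`` is given) off the required resolution.
    """
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"expected a 3-D scalar image, got shape {img.shape}")
    img = nib.as_closest_canonical(img)
    grid = _grid_from_header(img, iso_tolerance=iso_tolerance,
                             expected_voxel_size_mm=expected_voxel_size_mm)
    return ScalarVolume(grid=grid, intensities=np.asarray(img.get_fdata(), dtype=float))


def write_volume(volume: ScalarVolume, path) -> None:
    img = nib.Nifti1Image(volume.intensities.astype(np.float64), volume.grid.affine())
    nib.save(img, str(path))


def read_mask(path, grid: VolumeGrid) -> VoxelMask:
    """Read a NIfTI mask; any nonzero voxel is a member.

    The image must match ``grid``'s shape; probabilistic or multi-valued masks
    are binarized by nonzero membership (no thresholding).
    """
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asarray(img.get_fdata())
    if data.shape != grid.shape:
        raise ValueError(
            f"mask shape {data.shape} does not match grid shape {grid.shape}"
        )
    return VoxelMask(grid=grid, data=data != 0)


def write_mask(mask: VoxelMask, path) -> None:
    """Write a mask as unsigned 8-bit {0,1} NIfTI."""
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.grid.affine())
    nib.save(img, str(path))


def mask_volume_mm3(mask: VoxelMask) -> float:
    """Mask volume: voxel count times the voxel volume (exact)."""
    return mask.voxel_count * mask.grid.voxel_size_mm ** 3


def mask_extent_mm(mask: VoxelMask, axis: str) -> float:
    """Inclusive slab extent of the mask along ``axis`` ('x', 'y' or 'z').

    ``(max_index - min_index + 1) * voxel_size_mm``, so a single-voxel mask
    has extent equal to the voxel size, not zero.
    """
    if mask.voxel_count == 0:
        raise ValueError("extent of an empty mask is undefined")
    ax = _AXIS_INDEX[axis]
    coords = mask.indices[:, ax]
    return float((coords.max() - coords.min() + 1) * mask.grid.voxel_size_mm)
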
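"""3-D volume and binary-mask data model with NIfTI-1 I/O.

All images handled by the pipeline are plain 3-D scalar grids with a 4x4
voxel-to-world affine in millimetres.  Paired stages (MT / non-MT division,
mask intersection, measurement) require their inputs to live on one grid;
:func:`check_same_grid` is the predicate every such stage calls.  Data are
promoted to 64-bit float internally regardless of the on-disk type.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Tuple

import nibabel as nib
import numpy as np

from .errors import DimensionalityError, GridMismatchError, NormalizationError

#: default elementwise tolerance (mm) when comparing affines
GRID_TOL = 1e-4


def _voxel_size_from_affine(affine: np.ndarray) -> Tuple[float, float, float]:
    """Voxel edge lengths in mm: norms of the affine's three spatial columns."""
    return tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))


@dataclass
class VolumeGrid:
    """A 3-D scalar image together with its voxel-to-world transform.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar values; stored as float64.  NaN is allowed (voxels excluded
        by a validity mask), infinities are not.
    affine : ndarray, shape (4, 4)
        Voxel-index to world-mm transform (NIfTI convention, RAS+ assumed
        for laterality logic downstream).
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3-D volume, got {self.data.ndim}-D"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if np.isinf(self.data).any():
            raise ValueError("volume contains infinities")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must all be positive")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size(self) -> Tuple[float, float, float]:
        """Edge lengths (mm) of one voxel, derived from the affine."""
        return _voxel_size_from_affine(self.affine)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def axis_labels(self) -> Tuple[str, str, str]:
        """Anatomical orientation codes of the three data axes (e.g. R/A/S)."""
        return nib.orientations.aff2axcodes(self.affine)

    def world_coordinates(self) -> np.ndarray:
        """World (mm) coordinates of every voxel centre, shape (3, nx, ny, nz)."""
        idx = np.indices(self.shape, dtype=np.float64)
        out = np.einsum("ab,b...->a...", self.affine[:3, :3], idx)
        return out + self.affine[:3, 3][:, None, None, None]


@dataclass
class BinaryMask:
    """A boolean mask bound to the geometry of a reference grid.

    ``label`` is a provenance tag (``fourth_ventricle``, ``brainstem``,
    ``whole_brain``, ``lc``, ``truth_*`` ...).
    """

    data: np.ndarray
    affine: np.ndarray
    label: str = "mask"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3-D mask, got {self.data.ndim}-D"
            )

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size(self) -> Tuple[float, float, float]:
        return _voxel_size_from_affine(self.affine)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        """count x voxel volume; e.g. 0.08 mm^3 per voxel at 0.4x0.4x0.5."""
        return self.n_voxels * float(np.prod(self.voxel_size))

    def is_empty(self) -> bool:
        return not self.data.any()


def read_volume(path: os.PathLike | str) -> VolumeGrid:
    """Load a 3-D NIfTI-1 volume (scl_slope/scl_inter applied)."""
    img = nib.load(os.fspath(path))
    if len(img.shape) != 3:
        raise DimensionalityError(
            f"{path}: expected a 3-D image, got shape {img.shape}"
        )
    data = np.asarray(img.get_fdata(dtype=np.float64))
    return VolumeGrid(data=data, affine=np.asarray(img.affine))


def read_mask(path: os.PathLike | str, label: str = "mask") -> BinaryMask:
    """Load a binary mask stored as a uint8 {0,1} NIfTI volume."""
    vol = read_volume(path)
    return BinaryMask(data=vol.data > 0.5, affine=vol.affine, label=label)


def write_volume(vol: VolumeGrid, path: os.PathLike | str,
                 dtype=np.float32) -> None:
    img = nib.Nifti1Image(vol.data.astype(dtype), vol.affine)
    nib.save(img, os.fspath(path))


def write_mask(mask: BinaryMask, path: os.PathLike | str) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine)
    nib.save(img, os.fspath(path))


def check_same_grid(a, b, tol: float = GRID_TOL) -> bool:
    """True iff the two images share shape and affine (elementwise tol, mm).

    Pure predicate: accepts any two objects carrying ``shape``/``affine``
    (``VolumeGrid`` or ``BinaryMask``).
    """
    if tuple(a.shape) != tuple(b.shape):
        return False
    return bool(np.all(np.abs(np.asarray(a.affine) - np.asarray(b.affine)) <= tol))


def require_same_grid(a, b, tol: float = GRID_TOL, what: str = "volumes") -> None:
    """Raise :class:`GridMismatchError` unless the two images share a grid."""
    if not check_same_grid(a, b, tol=tol):
        raise GridMismatchError(
            f"incompatible grid: {what} differ in shape or affine "
            f"(shapes {tuple(a.shape)} vs {tuple(b.shape)})"
        )


def mask_volume_mm3(mask: BinaryMask) -> float:
    return mask.volume_mm3


def require_nonempty(mask: BinaryMask, what: str = "mask") -> None:
    if mask.is_empty():
        raise NormalizationError(f"{what} is empty")
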
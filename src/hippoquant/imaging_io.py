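"""Image data model and NIfTI-1 I/O.

All volumes in the package live on an explicit 3D grid: a scalar lattice, a
per-axis voxel size in mm, and a 4x4 voxel-index -> world-mm affine in the
RAS+ convention (x grows to the subject's right, y to anterior, z to
superior). Files in any other orientation are re-expressed in RAS+ on load,
leaving each voxel's world position unchanged. Voxel indices are 0-based and
a voxel's world position is the affine image of its integer index
(voxel-centre convention).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Any

import nibabel as nib
import numpy as np

__all__ = [
    "Volume3D",
    "LabelMask",
    "ImagingIOError",
    "MissingFileError",
    "DimensionalityError",
    "HeaderError",
    "MaskValueError",
    "GridMismatchError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "assert_same_grid",
]

#: absolute tolerance on affine entries when deciding two grids are the same;
#: absorbs header float noise without hiding genuine misregistration.
GRID_ATOL = 1e-5


class ImagingIOError(Exception):
    """Base class for image I/O and grid failures."""


class MissingFileError(ImagingIOError):
    """The requested path does not exist."""


class DimensionalityError(ImagingIOError):
    """The image is not a 3D volume."""


class HeaderError(ImagingIOError):
    """The file is not a readable NIfTI-1 image."""


class MaskValueError(ImagingIOError):
    """A label mask contains values other than 0 and 1."""


class GridMismatchError(ImagingIOError):
    """Two images do not share one grid (shape or affine differ)."""


def _spacing_from_affine(affine: np.ndarray) -> np.ndarray:
    return np.linalg.norm(affine[:3, :3], axis=0)


@dataclass
class Volume3D:
    """A 3D scalar image with voxel spacing and a voxel-to-world affine.

    Parameters
    ----------
    data:
        3D scalar lattice, arbitrary units.
    affine:
        4x4 voxel-index -> world-mm map, RAS+ world convention.
    meta:
        Free-form key/value metadata (e.g. ``te_ms``, ``description``).
    """

    data: np.ndarray
    affine: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D lattice, got {self.data.ndim}D shape {self.data.shape}"
            )
        if min(self.data.shape) < 1:
            raise DimensionalityError(f"degenerate shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise HeaderError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise HeaderError("affine is singular")
        if np.any(self.spacing <= 0):
            raise HeaderError(f"non-positive voxel spacing {self.spacing}")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return _spacing_from_affine(self.affine)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3 (parallelepiped determinant)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_coords(self, idx: np.ndarray) -> np.ndarray:
        """World-mm positions of an (n, 3) array of 0-based voxel indices."""
        idx = np.atleast_2d(idx)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class LabelMask(Volume3D):
    """A binary mask on the same grid as its companion volumes."""

    side: str = "left"

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise MaskValueError(f"mask values must be exactly 0/1, found {vals[:8]}")
        self.data = self.data.astype(np.uint8)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def _load_canonical(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray, nib.Nifti1Image]:
    if not os.path.exists(path):
        raise MissingFileError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise HeaderError(f"not a readable NIfTI image: {path} ({exc})") from exc
    if img.ndim != 3:
        raise DimensionalityError(f"{path}: expected 3D image, got {img.ndim}D")
    # Re-express in RAS+ (axis flips/permutations only; world positions kept).
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    return data, np.asarray(img.affine, dtype=float), img


def read_volume(path: str | os.PathLike) -> Volume3D:
    """Read a NIfTI-1 volume, normalised to the RAS+ world convention.

    Raises
    ------
    MissingFileError, DimensionalityError, HeaderError
    """
    data, affine, img = _load_canonical(path)
    meta = {"description": bytes(img.header["descrip"]).decode(errors="replace").strip("\x00")}
    return Volume3D(data=np.asarray(data, dtype=float), affine=affine, meta=meta)


def read_mask(path: str | os.PathLike, side: str) -> LabelMask:
    """Read a binary hippocampus mask; values must be exactly 0/1."""
    data, affine, _ = _load_canonical(path)
    return LabelMask(data=np.asarray(data), affine=affine, side=side)


def write_volume(v: Volume3D, path: str | os.PathLike) -> None:
    """Write a volume (or mask) as NIfTI-1; round-trips through read_volume."""
    directory = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(directory):
        raise MissingFileError(f"directory does not exist: {directory}")
    data = v.data
    if isinstance(v, LabelMask):
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, v.affine)
    img.header.set_zooms(tuple(v.spacing))
    nib.save(img, str(path))


write_mask = write_volume


def assert_same_grid(a: Volume3D, b: Volume3D) -> None:
    """Raise GridMismatchError unless a and b share shape and affine.

    Affine agreement is element-wise within GRID_ATOL; the error names the
    differing attribute. Symmetric in its arguments.
    """
    if a.shape != b.shape:
        raise GridMismatchError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not np.allclose(a.affine, b.affine, atol=GRID_ATOL, rtol=0.0):
        diff = np.abs(a.affine - b.affine).max()
        raise GridMismatchError(f"affine mismatch: max |delta| = {diff:g} > {GRID_ATOL:g}")
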
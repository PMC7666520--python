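"""Spatial data model: grids, scalar volumes, binary masks, sphere seeds.

Volumes live on a :class:`VolumeGrid` — a voxel lattice with a 4x4 affine
mapping grid indices to world millimetres (RAS, the MNI convention). All
analyses in this package require their inputs to share a grid *exactly*;
a resampling utility is provided but never applied implicitly, so silent
misregistration cannot occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import DomainError, EmptyROIError, FormatError, GridError

__all__ = [
    "VolumeGrid",
    "ScalarVolume",
    "BinaryMask",
    "SphereSeed",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "make_sphere_mask",
    "binarize_template",
    "gaussian_smooth",
    "resample_to_grid",
]

_GRID_ATOL = 1e-6  # mm tolerance for grid equality


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D voxel lattice with an index→world-mm affine.

    Parameters
    ----------
    shape : tuple of int
        Voxels per axis.
    affine : (4, 4) ndarray
        Homogeneous transform taking (i, j, k, 1) voxel indices to world
        millimetres. Must be invertible.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        affine = np.asarray(self.affine, dtype=float)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise DomainError(f"grid shape must be a positive triple, got {shape}")
        if affine.shape != (4, 4):
            raise DomainError("affine must be 4x4")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise DomainError("affine is singular")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)
        if np.any(self.spacing <= 0):
            raise DomainError("voxel spacing must be strictly positive")

    @property
    def spacing(self) -> np.ndarray:
        """Voxel size in mm per axis (column norms of the linear part)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VolumeGrid):
            return NotImplemented
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=_GRID_ATOL
        )

    def __hash__(self) -> int:
        return hash(self.shape)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to (n, 3) world mm."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map (n, 3) world mm to (n, 3) fractional voxel indices."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def coordinate_image(self) -> np.ndarray:
        """World mm of every voxel center, shape ``(*shape, 3)``."""
        idx = np.indices(self.shape, dtype=float)
        ijk = idx.reshape(3, -1).T
        return self.voxel_to_world(ijk).reshape(*self.shape, 3)


def _check_same_grid(*grids: VolumeGrid) -> None:
    first = grids[0]
    for g in grids[1:]:
        if g != first:
            raise GridError(
                f"grids differ: shape {first.shape} vs {g.shape} or affines diverge"
            )


@dataclass
class ScalarVolume:
    """A scalar value per voxel on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GridError(
                f"value array shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.grid, self.values.copy())


@dataclass
class BinaryMask:
    """A boolean membership per voxel on a :class:`VolumeGrid`."""

    grid: VolumeGrid
    membership: np.ndarray

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership).astype(bool)
        if self.membership.shape != self.grid.shape:
            raise GridError(
                f"mask shape {self.membership.shape} != grid shape {self.grid.shape}"
            )

    @property
    def n_true(self) -> int:
        return int(self.membership.sum())

    def require_nonempty(self, what: str = "mask") -> "BinaryMask":
        if self.n_true == 0:
            raise EmptyROIError(f"{what} contains no voxels")
        return self

    def intersect(self, other: "BinaryMask") -> "BinaryMask":
        _check_same_grid(self.grid, other.grid)
        return BinaryMask(self.grid, self.membership & other.membership)

    def minus(self, other: "BinaryMask") -> "BinaryMask":
        _check_same_grid(self.grid, other.grid)
        return BinaryMask(self.grid, self.membership & ~other.membership)

    def union(self, other: "BinaryMask") -> "BinaryMask":
        _check_same_grid(self.grid, other.grid)
        return BinaryMask(self.grid, self.membership | other.membership)


@dataclass(frozen=True)
class SphereSeed:
    """A named spherical seed ROI defined in world (MNI) millimetres."""

    name: str
    center_mni: tuple[float, float, float]
    radius_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise DomainError(f"seed radius must be > 0, got {self.radius_mm}")
        object.__setattr__(self, "center_mni", tuple(float(c) for c in self.center_mni))


# --------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path) -> ScalarVolume:
    """Read a single-volume NIfTI-1/2 image as a :class:`ScalarVolume`."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    if not isinstance(img, (nib.Nifti1Image, nib.Nifti2Image)):
        raise FormatError(f"{path} is not a NIfTI-1/2 image ({type(img).__name__})")
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise FormatError(f"{path} is not a single 3-D volume (shape {data.shape})")
    grid = VolumeGrid(tuple(data.shape), np.asarray(img.affine, dtype=float))
    return ScalarVolume(grid, data.astype(float))


def write_volume(volume: ScalarVolume, path) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float64), volume.grid.affine)
    nib.save(img, str(path))


def read_mask(path) -> BinaryMask:
    """Read a 0/1-coded NIfTI volume as a :class:`BinaryMask`."""
    vol = read_volume(path)
    return BinaryMask(vol.grid, vol.values > 0.5)


def write_mask(mask: BinaryMask, path) -> None:
    img = nib.Nifti1Image(mask.membership.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))


# --------------------------------------------------------------------------
# Mask construction


def make_sphere_mask(grid: VolumeGrid, seed: SphereSeed) -> BinaryMask:
    """Rasterize a seed sphere: a voxel is a member iff its *center* lies
    within ``radius_mm`` (Euclidean, world space) of the seed center."""
    coords = grid.coordinate_image()
    d2 = np.sum((coords - np.asarray(seed.center_mni)) ** 2, axis=-1)
    member = d2 <= seed.radius_mm**2
    if not member.any():
        raise EmptyROIError(
            f"sphere '{seed.name}' at {seed.center_mni} r={seed.radius_mm}mm "
            "rasterizes to zero voxels on this grid"
        )
    return BinaryMask(grid, member)


def binarize_template(continuous_map: ScalarVolume, threshold: float) -> BinaryMask:
    """Binarize a continuous map at a strict ``value > threshold`` cut.

    Used to turn correlation-style network maps (e.g. thresholded at
    r = 0.2) into binary template masks.
    """
    if np.isnan(threshold):
        raise DomainError("threshold must not be NaN")
    member = continuous_map.values > threshold
    mask = BinaryMask(continuous_map.grid, member)
    return mask.require_nonempty("binarized template")


# --------------------------------------------------------------------------
# Smoothing and resampling

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


def gaussian_smooth(volume: ScalarVolume, fwhm_mm) -> ScalarVolume:
    """Separable Gaussian smoothing with a FWHM given in millimetres.

    ``sigma`` per axis is ``fwhm / (spacing * sqrt(8 ln 2))`` voxels; the
    boundary condition is symmetric reflection, which preserves the global
    mean. A FWHM of 0 on an axis leaves that axis untouched.
    """
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,))
    if np.any(fwhm < 0):
        raise DomainError(f"fwhm components must be >= 0, got {tuple(fwhm)}")
    if np.all(fwhm == 0):
        return volume.copy()
    sigma_vox = fwhm * FWHM_TO_SIGMA / volume.grid.spacing
    out = ndimage.gaussian_filter(volume.values, sigma=sigma_vox, mode="reflect")
    return ScalarVolume(volume.grid, out)


def resample_to_grid(volume: ScalarVolume, grid: VolumeGrid, order: int = 1) -> ScalarVolume:
    """Resample a volume onto another grid through world space.

    order=0 is nearest-neighbour (use for masks), order=1 trilinear. This
    is an explicit utility: no analysis in the package resamples for you.
    """
    xyz = grid.coordinate_image().reshape(-1, 3)
    ijk = volume.grid.world_to_voxel(xyz)
    vals = ndimage.map_coordinates(
        volume.values, ijk.T, order=order, mode="nearest"
    )
    return ScalarVolume(grid, vals.reshape(grid.shape))
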
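"""Volumetric data model, mask logic, vectorization and NIfTI I/O.

All cross-volume operations in this package require volumes to live on an
identical grid (same shape, same affine); no resampling is performed.
Vectorization uses a fixed, documented voxel ordering — ascending linear
index with the *first* axis fastest (Fortran order) — so that dot products
between vectorized maps are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "BrainVolume",
    "BinaryMask",
    "SignaturePattern",
    "VoxelVector",
    "GridMismatchError",
    "EmptyMaskError",
    "read_volume",
    "write_volume",
    "vectorize",
    "devectorize",
    "joint_valid_mask",
]


class GridMismatchError(ValueError):
    """Volumes entering a joint computation do not share a grid."""


class EmptyMaskError(ValueError):
    """A mask (or mask intersection) selects no voxels."""


@dataclass
class BrainVolume:
    """A 3-D numeric grid with spatial metadata.

    Carrier of contrast maps, weight maps and statistic maps. ``data`` is a
    float array; non-finite values are allowed (they mark voxels with no
    coverage) and are excluded from joint computations via
    :func:`joint_valid_mask`.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D data, got {self.data.ndim}-D")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm per axis (from the affine)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def same_grid(self, other: "BrainVolume | BinaryMask") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=1e-6
        )


@dataclass
class BinaryMask:
    """A {0,1} volume on the same grid convention as :class:`BrainVolume`."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    name: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected 3-D mask, got {arr.ndim}-D")
        uniq = np.unique(arr[np.isfinite(arr.astype(float))])
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be 0/1")
        self.data = arr.astype(bool)
        if self.data.sum() == 0:
            raise EmptyMaskError("mask selects no voxels")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def same_grid(self, other) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=1e-6
        )

    def is_subset_of(self, other: "BinaryMask") -> bool:
        return bool(np.all(other.data[self.data]))


@dataclass
class SignaturePattern:
    """A named multivariate weight map (e.g. an NPS-like pattern)."""

    volume: BrainVolume
    name: str = "signature"

    def norm_within(self, mask: BinaryMask) -> float:
        vals = self.volume.data[mask.data]
        vals = vals[np.isfinite(vals)]
        return float(np.sqrt((vals**2).sum()))


@dataclass
class VoxelVector:
    """Masked voxel values plus the index map back to grid coordinates.

    ``indices`` are linear indices in Fortran order (first axis fastest),
    ascending — the package-wide voxel ordering.
    """

    values: np.ndarray
    indices: np.ndarray
    shape: tuple[int, int, int]

    def __len__(self) -> int:
        return len(self.values)


def read_volume(path, name: str | None = None) -> BrainVolume:
    """Read a 3-D NIfTI-1 volume.

    Raises a format error for unreadable files and an explicit "expected
    3-D" error for 4-D images (first-level time series are out of scope).
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise IOError(f"could not read NIfTI file {path!r}: {exc}") from exc
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"expected 3-D volume, got {data.ndim}-D with shape {data.shape}"
        )
    return BrainVolume(data=data, affine=img.affine, name=name or str(path))


def write_volume(volume: BrainVolume | BinaryMask, path) -> None:
    """Write a volume or mask as NIfTI-1."""
    data = volume.data.astype(np.uint8) if isinstance(volume, BinaryMask) else volume.data
    nib.Nifti1Image(data, volume.affine).to_filename(str(path))


def read_mask(path, name: str | None = None) -> BinaryMask:
    vol = read_volume(path, name=name)
    return BinaryMask(data=vol.data > 0.5, affine=vol.affine, name=vol.name)


def _check_grid(a, b) -> None:
    if not a.same_grid(b):
        raise GridMismatchError(
            f"grid mismatch: {a.shape} vs {b.shape} (or affines differ)"
        )


def vectorize(
    volume: BrainVolume, mask: BinaryMask, drop_nonfinite: bool = False
) -> VoxelVector:
    """Extract masked voxels as an ordered vector.

    Ordering is ascending linear index with the first axis fastest. With
    ``drop_nonfinite`` only finite masked voxels are kept.
    """
    _check_grid(volume, mask)
    flat = volume.data.ravel(order="F")
    idx = np.flatnonzero(mask.data.ravel(order="F"))
    if idx.size == 0:
        raise EmptyMaskError("mask selects no voxels")
    vals = flat[idx]
    if drop_nonfinite:
        keep = np.isfinite(vals)
        vals, idx = vals[keep], idx[keep]
        if idx.size == 0:
            raise EmptyMaskError("no finite voxels under mask")
    return VoxelVector(values=vals, indices=idx, shape=volume.shape)


def devectorize(vector: VoxelVector, affine: np.ndarray | None = None) -> BrainVolume:
    """Scatter a voxel vector back onto its grid; unmasked voxels become NaN."""
    flat = np.full(int(np.prod(vector.shape)), np.nan)
    flat[vector.indices] = vector.values
    data = flat.reshape(vector.shape, order="F")
    return BrainVolume(data=data, affine=np.eye(4) if affine is None else affine)


def joint_valid_mask(volumes: list[BrainVolume], base_mask: BinaryMask) -> BinaryMask:
    """Voxels finite in *every* volume and inside ``base_mask``.

    Needed because maps pooled across studies have different coverage; all
    similarity and GLM stages operate on this joint valid mask.
    """
    keep = base_mask.data.copy()
    for vol in volumes:
        _check_grid(vol, base_mask)
        keep &= np.isfinite(vol.data)
    if keep.sum() == 0:
        raise EmptyMaskError("joint valid mask is empty")
    return BinaryMask(data=keep, affine=base_mask.affine, name="joint_valid")
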
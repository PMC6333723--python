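"""Volumetric data model and NIfTI-1 I/O.

PET activity values are treated as arbitrary units throughout: every
downstream decision (edge thresholds, display windows, regional grades)
is ratio- or window-based, so volumes carry floating-point samples and no
absolute calibration. Voxel indices are 0-based; world coordinates are
RAS+ millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


class VolumeFormatError(ValueError):
    """A file or header does not describe a usable 3D volume."""


class DegenerateInputError(ValueError):
    """An input volume or mask carries no usable signal."""


@dataclass
class Volume:
    """A 3D intensity grid with a grid-to-world affine.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Nonnegative intensities in arbitrary activity units.
    affine : ndarray, shape (4, 4)
        Grid-index (0-based) to RAS+ millimetre transform.
    phase : {"early", "late", "none"}
        Acquisition phase tag: "early" for the perfusion frame acquired
        immediately after tracer injection, "late" for the amyloid-binding
        frame, "none" for derived or untagged volumes.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    phase: str = "none"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"volume must be 3D, got {self.data.ndim}D shape {self.data.shape}"
            )
        if self.affine.shape != (4, 4):
            raise VolumeFormatError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise VolumeFormatError("affine (world_map) is singular")
        if self.phase not in ("early", "late", "none"):
            raise VolumeFormatError(f"unknown phase tag {self.phase!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def with_data(self, data: np.ndarray, phase: str | None = None) -> "Volume":
        return Volume(data, self.affine.copy(), phase if phase is not None else self.phase)

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.affine.copy(), self.phase)

    def world_center(self) -> np.ndarray:
        """World coordinates of the grid centre (the rotation pivot)."""
        center_idx = (np.asarray(self.shape, float) - 1.0) / 2.0
        return self.affine[:3, :3] @ center_idx + self.affine[:3, 3]


@dataclass
class Mask:
    """A binary grid aligned to a Volume (same shape and affine)."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise VolumeFormatError("mask must be 3D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())


def read_volume(path: str | Path, phase: str = "none") -> Volume:
    """Read a 3D NIfTI-1 file (.nii or .nii.gz), reoriented to RAS+.

    Raises
    ------
    VolumeFormatError
        If the file is not 3D or carries non-finite voxel sizes.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad files
        raise VolumeFormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    if len(img.shape) != 3:
        raise VolumeFormatError(
            f"{path}: expected a 3D image, got shape {tuple(img.shape)}"
        )
    img = nib.as_closest_canonical(img)
    zooms = np.asarray(img.header.get_zooms()[:3], float)
    if not np.all(np.isfinite(zooms)) or np.any(zooms <= 0):
        raise VolumeFormatError(f"{path}: non-finite or nonpositive voxel spacing {zooms}")
    data = np.asarray(img.get_fdata(), dtype=float)
    return Volume(data, np.asarray(img.affine, float), phase)


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a Volume as NIfTI-1 with an RAS+ affine."""
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise IOError(f"cannot write NIfTI file {path}: {exc}") from exc


def resample(
    volume: Volume,
    target_shape: tuple[int, int, int],
    target_affine: np.ndarray,
    order: int = 1,
) -> Volume:
    """Resample onto a new grid by trilinear interpolation in world space.

    Points falling outside the source grid are filled with zero.
    """
    target_affine = np.asarray(target_affine, float)
    if abs(np.linalg.det(target_affine[:3, :3])) < 1e-12:
        raise ValueError("target world map is singular")
    # source_index = inv(A_src) @ A_tgt @ target_index
    M = np.linalg.inv(volume.affine) @ target_affine
    out = ndimage.affine_transform(
        volume.data,
        M[:3, :3],
        offset=M[:3, 3],
        output_shape=tuple(target_shape),
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=order > 1,
    )
    return Volume(out, target_affine, volume.phase)


def robust_max(volume: Volume, percentile: float = 0.99) -> float:
    """Upper intensity summary: percentile of the positive samples.

    Using only positive voxels ignores the empty background that dominates
    brain PET grids; the 99th percentile is insensitive to isolated hot
    voxels from count noise.
    """
    if not 0 < percentile <= 1:
        raise ValueError(f"percentile must be in (0, 1], got {percentile}")
    positive = volume.data[volume.data > 0]
    if positive.size == 0:
        raise DegenerateInputError("volume has no positive intensities")
    return float(np.quantile(positive, percentile))
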
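"""Volumetric I/O for spatially normalized PET images and VOI masks.

All images are single-frame 3D NIfTI-1 volumes already on a common template
grid (MNI-152 mm space via the header affine). This module deliberately does
no resampling: a grid mismatch between an image and a mask is a hard error,
because silent interpolation changes region means and therefore SUVR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "VoiMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "check_same_grid",
    "GridMismatchError",
]

#: Default absolute tolerance for elementwise affine agreement.
DEFAULT_AFFINE_TOL = 1e-4

#: Default weight threshold separating in-region from out-of-region voxels.
DEFAULT_MASK_THRESHOLD = 0.5


class GridMismatchError(ValueError):
    """Two volumes/masks do not share dims and affine; no resampling is done."""


@dataclass
class VolumeGrid:
    """A 3D uptake image with spatial metadata.

    Voxel values are unitless activity (SUVR is scale-invariant, so no
    dose/body-weight normalization is applied). Non-finite voxels are
    flagged missing and excluded from all downstream statistics.
    """

    values: np.ndarray          # 3D float array; missing voxels hold NaN
    affine: np.ndarray          # 4x4 voxel-to-world (MNI-152 mm)
    missing: np.ndarray = field(default=None)  # 3D bool, True where absent

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.values.ndim}D")
        if any(d < 1 for d in self.values.shape):
            raise ValueError("all dims must be >= 1")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if self.missing is None:
            self.missing = ~np.isfinite(self.values)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            self.missing |= ~np.isfinite(self.values)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm, from the affine column norms."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class VoiMask:
    """Per-voxel weight map in [0, 1] defining a volume of interest.

    Weights are stored continuously but all region statistics in this
    package use the binary view (``weight >= threshold``): the standard
    Centiloid VOIs are distributed as masks and no weighting rule exists.
    """

    weights: np.ndarray
    affine: np.ndarray
    name: str = "VOI"
    threshold: float = DEFAULT_MASK_THRESHOLD

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.weights.ndim}D")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.weights.min() < 0 or self.weights.max() > 1:
            raise ValueError("mask weights must lie in [0, 1]")
        if not np.any(self.weights > 0):
            raise ValueError(f"empty VOI: mask '{self.name}' has no positive weights")
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must lie in [0, 1]")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.weights.shape

    @property
    def binary(self) -> np.ndarray:
        """Boolean in-region view at the configured threshold."""
        return self.weights >= self.threshold


def _load_3d(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    # tolerate trailing singleton frames, reject real 4D data
    data = np.squeeze(data)
    if data.ndim == 4:
        raise ValueError(
            f"expected 3D volume, got 4D with {data.shape[3]} frames "
            f"({path}); pre-average frames before quantification"
        )
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D ({path})")
    return np.asarray(data, dtype=np.float64), np.asarray(img.affine, dtype=np.float64)


def read_volume(path: str | Path) -> VolumeGrid:
    """Read a single-frame 3D NIfTI-1 uptake image.

    The header affine (sform preferred, nibabel's default fallback chain)
    is authoritative for world coordinates. Non-finite voxels are flagged
    missing so no NaN leaks into region statistics.
    """
    data, affine = _load_3d(path)
    return VolumeGrid(values=data, affine=affine)


def write_volume(volume: VolumeGrid, path: str | Path) -> None:
    """Write a volume as float64 NIfTI-1 (bit-exact value round-trip)."""
    img = nib.Nifti1Image(volume.values.astype(np.float64), volume.affine)
    nib.save(img, str(path))


def read_mask(
    path: str | Path,
    threshold: float = DEFAULT_MASK_THRESHOLD,
    name: str | None = None,
) -> VoiMask:
    """Read a VOI mask, normalizing stored values to weights in [0, 1].

    Masks coded on other scales (e.g. 0/255 label volumes) are rescaled by
    their maximum before clamping, so binary masks stay binary. A mask with
    no positive weight is rejected as an empty VOI.
    """
    data, affine = _load_3d(path)
    if np.any(~np.isfinite(data)):
        data = np.nan_to_num(data, nan=0.0, posinf=0.0, neginf=0.0)
    mx = data.max()
    if mx > 1.0:
        data = data / mx
    data = np.clip(data, 0.0, 1.0)
    if not np.any(data > 0):
        raise ValueError(f"empty VOI: mask {path} has no positive weights")
    return VoiMask(
        weights=data,
        affine=affine,
        name=name or Path(path).name,
        threshold=threshold,
    )


def write_mask(mask: VoiMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.weights.astype(np.float64), mask.affine)
    nib.save(img, str(path))


def check_same_grid(
    a: VolumeGrid | VoiMask,
    b: VolumeGrid | VoiMask,
    affine_tol: float = DEFAULT_AFFINE_TOL,
) -> bool:
    """True iff dims match exactly and affines agree elementwise within tol.

    Pure predicate; callers that require agreement raise GridMismatchError.
    """
    if tuple(a.dims) != tuple(b.dims):
        return False
    return bool(np.all(np.abs(a.affine - b.affine) <= affine_tol))


def require_same_grid(
    a: VolumeGrid | VoiMask,
    b: VolumeGrid | VoiMask,
    what: str = "inputs",
    affine_tol: float = DEFAULT_AFFINE_TOL,
) -> None:
    if not check_same_grid(a, b, affine_tol=affine_tol):
        raise GridMismatchError(
            f"{what} are not on the same grid (dims {tuple(a.dims)} vs "
            f"{tuple(b.dims)}); resampling is not performed by this package"
        )
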
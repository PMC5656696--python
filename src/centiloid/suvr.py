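"""Region statistics and SUVR with the whole cerebellum as reference.

SUVR is the ratio of the mean uptake in the cortical target VOI to the mean
uptake in the reference VOI (ratio-of-means convention). Missing voxels are
excluded from the means, never zero-filled, since zero-filling would bias
SUVR downward. Partial volume correction is not performed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .volume_io import VoiMask, VolumeGrid, require_same_grid

__all__ = ["RegionStats", "SuvrRecord", "region_mean", "compute_suvr"]


@dataclass(frozen=True)
class RegionStats:
    """Summary of uptake over the binary view of one VOI."""

    voxel_count: int
    mean: float
    sd: float                 # population SD over in-region voxels
    missing_excluded: int

    def __post_init__(self) -> None:
        if self.voxel_count < 1:
            raise ValueError("region must contain at least one usable voxel")
        if not np.isfinite(self.mean):
            raise ValueError("region mean is not finite")


@dataclass(frozen=True)
class SuvrRecord:
    """One subject x tracer SUVR with its numerator/denominator means."""

    subject_id: str
    tracer: str               # "PiB", "FBB", or another tracer label
    target_mean: float
    reference_mean: float
    suvr: float

    def __post_init__(self) -> None:
        if self.reference_mean <= 0:
            raise ValueError("invalid reference region: mean must be > 0")
        if self.suvr <= 0:
            raise ValueError("SUVR must be > 0")

    @classmethod
    def from_means(
        cls, subject_id: str, tracer: str, target_mean: float, reference_mean: float
    ) -> "SuvrRecord":
        return cls(
            subject_id=subject_id,
            tracer=tracer,
            target_mean=float(target_mean),
            reference_mean=float(reference_mean),
            suvr=float(target_mean) / float(reference_mean),
        )

    def as_row(self) -> dict:
        return asdict(self)


def region_mean(volume: VolumeGrid, mask: VoiMask) -> RegionStats:
    """Mean and SD of uptake over the binary mask view, skipping missing voxels.

    Raises GridMismatchError when image and mask are not on the same grid,
    and ValueError when every in-mask voxel is missing.
    """
    require_same_grid(volume, mask, what=f"volume and mask '{mask.name}'")
    sel = mask.binary
    usable = sel & ~volume.missing
    n_missing = int(np.count_nonzero(sel) - np.count_nonzero(usable))
    if not np.any(usable):
        raise ValueError(
            f"all {int(np.count_nonzero(sel))} voxels in mask '{mask.name}' are missing"
        )
    vals = volume.values[usable]
    return RegionStats(
        voxel_count=int(vals.size),
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=0)),
        missing_excluded=n_missing,
    )


def compute_suvr(
    volume: VolumeGrid,
    cortex: VoiMask,
    reference: VoiMask,
    subject_id: str,
    tracer: str,
) -> SuvrRecord:
    """SUVR = mean(cortex) / mean(whole-cerebellum reference).

    Raises ValueError("invalid reference region") when the reference mean
    is not positive.
    """
    target = region_mean(volume, cortex)
    ref = region_mean(volume, reference)
    if ref.mean <= 0:
        raise ValueError(
            f"invalid reference region '{reference.name}': mean {ref.mean:.4g} <= 0"
        )
    return SuvrRecord.from_means(subject_id, tracer, target.mean, ref.mean)
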
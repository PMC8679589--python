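"""Blood-pool reference statistics and the PERCIST admission threshold.

PERCIST-style lesion detection admits only regions whose SUVpeak exceeds a
patient-specific threshold derived from blood-pool uptake, measured in a small
cylinder placed in the proximal descending aorta:

    threshold = 2 * mean(blood pool SUV) + 2 * SD(blood pool SUV)

Aorta localization itself is out of scope here: the cylinder center comes
from the synthetic ground truth or from user configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UnreliableReferenceError
from .volume import SUVVolume, VoxelMask, cylinder_mask

#: PERCIST-practice defaults for the aortic reference cylinder (mm).
DEFAULT_CYLINDER_DIAMETER_MM = 10.0
DEFAULT_CYLINDER_LENGTH_MM = 20.0


@dataclass(frozen=True)
class ReferenceStats:
    """Blood-pool mean/SD and the derived SUVpeak admission threshold."""

    mean_suv: float
    sd_suv: float

    def __post_init__(self) -> None:
        if not self.mean_suv > 0:
            raise ValueError(f"blood-pool mean SUV must be > 0, got {self.mean_suv}")
        if self.sd_suv < 0:
            raise ValueError(f"blood-pool SUV SD must be >= 0, got {self.sd_suv}")

    @property
    def threshold_suvpeak(self) -> float:
        """Admission threshold: twice the blood-pool mean plus twice its SD."""
        return 2.0 * self.mean_suv + 2.0 * self.sd_suv


def blood_pool_stats(
    volume: SUVVolume,
    aorta_center_mm,
    diameter_mm: float = DEFAULT_CYLINDER_DIAMETER_MM,
    length_mm: float = DEFAULT_CYLINDER_LENGTH_MM,
    min_voxels: int = 10,
) -> ReferenceStats:
    """Mean and population SD of SUV over the aortic reference cylinder.

    Raises
    ------
    UnreliableReferenceError
        If the cylinder contains fewer than ``min_voxels`` voxels (spacing too
        coarse or cylinder clipped at the grid edge).
    """
    mask = cylinder_mask(volume, aorta_center_mm, diameter_mm, length_mm)
    return stats_in_mask(volume, mask, min_voxels=min_voxels)


def stats_in_mask(volume: SUVVolume, mask: VoxelMask, min_voxels: int = 10) -> ReferenceStats:
    """Reference statistics over an arbitrary mask (population SD, ddof=0)."""
    vals = volume.values[mask.data]
    if vals.size < min_voxels:
        raise UnreliableReferenceError(
            f"reference region has {vals.size} voxels, need >= {min_voxels}"
        )
    return ReferenceStats(mean_suv=float(np.mean(vals)), sd_suv=float(np.std(vals)))
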
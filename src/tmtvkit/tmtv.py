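"""Total metabolic tumor volume (TMTV) aggregation.

TMTV is the sum of the volumes of all candidate ROIs classified as suspicious
uptake, in cm^3. The volumes are the candidates' own (iso-contour) volumes,
i.e. TMTV is an *estimator* and is not read from any reference mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import ClassifiedROI
from .volume import VoxelMask


def compute_tmtv(classified: list[ClassifiedROI]) -> float:
    """Sum of suspicious ROI volumes in cm^3 (0 for empty / all-physiologic)."""
    return float(sum(c.volume_cm3 for c in classified if c.is_suspicious))


@dataclass
class SubjectResult:
    """Per-subject pipeline output."""

    subject_id: str
    settings_name: str
    rois: list[ClassifiedROI]
    tmtv_cm3: float
    ref_union: VoxelMask | None = None
    true_tmtv_cm3: float | None = None
    blood_pool: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = compute_tmtv(self.rois)
        if not np.isclose(self.tmtv_cm3, expected):
            raise ValueError(
                f"tmtv_cm3 {self.tmtv_cm3} does not equal the suspicious-volume sum {expected}"
            )

    @property
    def n_rois(self) -> int:
        return len(self.rois)

    @property
    def n_suspicious(self) -> int:
        return sum(1 for c in self.rois if c.is_suspicious)

    @property
    def suspicious_union(self) -> VoxelMask | None:
        """Voxel union of all suspicious ROIs (None when there are no ROIs at all)."""
        if not self.rois:
            return None
        first = self.rois[0].roi.mask
        data = np.zeros(first.shape, dtype=bool)
        for c in self.rois:
            if c.is_suspicious:
                data |= c.roi.mask.data
        return first.like(data)
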
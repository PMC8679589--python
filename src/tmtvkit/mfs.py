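"""Multi-foci segmentation (MFS): whole-body high-uptake candidate detection.

The detection pipeline mirrors PERCIST-style hot-spot segmentation:

1. **Seed detection** — connected components (26-neighborhood by default) of
   voxels at or above a seed level: the blood-pool SUVpeak threshold
   (``blood_pool_peak`` mode) or a fixed SUV (``fixed_suv`` mode, 2.5 by
   convention).
2. **Iso-contour refinement** — each seed component is re-segmented at a
   fraction of its own SUVmax (42% by default). When refinement splits a
   component, each connected piece that still reaches the seed level becomes
   its own candidate. Voxels are claimed at most once (components processed
   in decreasing-SUVmax order), so candidates are pairwise disjoint.
3. **Peak admission** (``blood_pool_peak`` mode only) — keep candidates whose
   SUVpeak (max over the ROI of the mean SUV in a 1-cm^3 sphere) is strictly
   greater than the blood-pool threshold.
4. **Volume filter** — drop candidates with volume strictly below the minimum
   (2 cm^3 by default; a candidate of exactly 2.000 cm^3 is kept).

Candidates are ordered by decreasing SUVmax (ties broken by lexicographic
centroid) with stable 1-based ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .blood_pool import ReferenceStats
from .errors import EmptyRegionError
from .volume import SUVVolume, VoxelMask, sphere_radius_mm


@dataclass(frozen=True)
class SegmentationSettings:
    """Tunable parameters of candidate detection.

    ``admission_mode`` selects the seed level: ``"blood_pool_peak"`` uses the
    patient-specific PERCIST threshold and additionally enforces the SUVpeak
    admission rule; ``"fixed_suv"`` seeds at ``fixed_suv_threshold`` with no
    peak admission.
    """

    admission_mode: str = "blood_pool_peak"
    fixed_suv_threshold: float = 2.5
    isocontour_fraction: float = 0.42
    min_volume_cm3: float = 2.0
    peak_sphere_volume_cm3: float = 1.0
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.admission_mode not in ("blood_pool_peak", "fixed_suv"):
            raise ValueError(f"unknown admission_mode {self.admission_mode!r}")
        if not 0 < self.isocontour_fraction < 1:
            raise ValueError("isocontour_fraction must be in (0, 1)")
        if self.min_volume_cm3 < 0:
            raise ValueError("min_volume_cm3 must be >= 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


#: Named presets: the default PERCIST-based setting and the two alternatives
#: (fixed SUV 2.5 seed with 41% iso-contour, with and without small ROIs).
PRESETS: dict[str, SegmentationSettings] = {
    "percist42": SegmentationSettings(),
    "suv2p5_41": SegmentationSettings(
        admission_mode="fixed_suv", fixed_suv_threshold=2.5, isocontour_fraction=0.41
    ),
    "suv2p5_41_small": SegmentationSettings(
        admission_mode="fixed_suv",
        fixed_suv_threshold=2.5,
        isocontour_fraction=0.41,
        min_volume_cm3=0.1,
    ),
}


@dataclass
class CandidateROI:
    """One connected high-uptake region."""

    id: int
    mask: VoxelMask
    suvmax: float
    suvpeak: float
    volume_cm3: float
    centroid_mm: tuple[float, float, float]
    extras: dict = field(default_factory=dict)

    def with_id(self, new_id: int) -> "CandidateROI":
        return replace(self, id=new_id)


def _structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, rank)


def sphere_offsets(spacing, sphere_volume_cm3: float) -> np.ndarray:
    """Integer index offsets whose voxel centers fall in a sphere at the origin."""
    r = sphere_radius_mm(sphere_volume_cm3)
    spacing = np.asarray(spacing, dtype=float)
    reach = np.floor(r / spacing).astype(int)
    ax = [np.arange(-reach[a], reach[a] + 1) for a in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    offs = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    d2 = np.sum((offs * spacing) ** 2, axis=1)
    return offs[d2 <= r * r]


def sphere_mean_at(values: np.ndarray, voxels: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Mean SUV in the offset-sphere centered at each voxel, clipped at the grid."""
    shape = np.asarray(values.shape)
    sums = np.zeros(len(voxels))
    counts = np.zeros(len(voxels))
    for off in offsets:
        pos = voxels + off
        ok = np.all((pos >= 0) & (pos < shape), axis=1)
        p = pos[ok]
        sums[ok] += values[p[:, 0], p[:, 1], p[:, 2]]
        counts[ok] += 1.0
    return sums / counts


def suv_peak(
    volume: SUVVolume, roi_mask: VoxelMask, sphere_volume_cm3: float = 1.0
) -> float:
    """SUVpeak: max over ROI voxels of the mean SUV in a ~1 cm^3 sphere.

    The sphere may extend beyond the ROI; it is clipped only at the grid
    boundary (the mean is then taken over the in-grid part).
    """
    voxels = np.argwhere(roi_mask.data)
    if len(voxels) == 0:
        raise EmptyRegionError("suv_peak of an empty mask")
    offs = sphere_offsets(volume.spacing, sphere_volume_cm3)
    return float(np.max(sphere_mean_at(volume.values, voxels, offs)))


def _argmax_in_mask(values: np.ndarray, mask: np.ndarray) -> tuple[int, int, int]:
    """Lexicographically smallest index attaining the max of values over mask."""
    vals = values[mask]
    m = vals.max()
    cand = np.argwhere(mask & (values == m))
    return tuple(cand[0])  # argwhere is C-ordered => lexicographic


def isocontour_region(
    volume: SUVVolume, seed_mask: VoxelMask, fraction: float, connectivity: int = 26
) -> VoxelMask:
    """Connected region above ``fraction * SUVmax(seed)`` containing the argmax.

    The SUVmax is taken over the seed mask (region-wise, not global); the
    returned region is the connected component of ``{SUV >= fraction * max}``
    that contains the (lexicographically first) maximizing voxel.
    """
    if not seed_mask.data.any():
        raise EmptyRegionError("isocontour_region of an empty seed mask")
    vstar = _argmax_in_mask(volume.values, seed_mask.data)
    level = fraction * volume.values[vstar]
    above = volume.values >= level
    labels, _ = ndimage.label(above, structure=_structure(connectivity))
    return seed_mask.like(labels == labels[vstar])


def detect_candidates(
    volume: SUVVolume,
    ref_stats: ReferenceStats | None,
    settings: SegmentationSettings,
) -> list[CandidateROI]:
    """Detect all high-uptake candidate ROIs in a whole-body SUV volume.

    ``ref_stats`` is required in ``blood_pool_peak`` mode (it sets both the
    seed level and the SUVpeak admission threshold) and ignored in
    ``fixed_suv`` mode.
    """
    vals = volume.values
    struct = _structure(settings.connectivity)
    if settings.admission_mode == "blood_pool_peak":
        if ref_stats is None:
            raise ValueError("blood_pool_peak mode requires reference statistics")
        seed_level = ref_stats.threshold_suvpeak
    else:
        seed_level = settings.fixed_suv_threshold

    seed_labels, n_seeds = ndimage.label(vals >= seed_level, structure=struct)
    if n_seeds == 0:
        return []

    # Process seed components in decreasing SUVmax order (ties: lexicographic
    # smallest voxel index) so overlap claims are deterministic.
    comp_order = []
    for lab in range(1, n_seeds + 1):
        comp = seed_labels == lab
        vstar = _argmax_in_mask(vals, comp)
        comp_order.append((-vals[vstar], vstar, lab))
    comp_order.sort()

    claimed = np.zeros(vals.shape, dtype=bool)
    raw: list[np.ndarray] = []
    for _negmax, _vstar, lab in comp_order:
        comp = (seed_labels == lab) & ~claimed
        if not comp.any():
            continue  # fully absorbed by an earlier component's refinement
        m = vals[comp].max()
        level = settings.isocontour_fraction * m
        above = (vals >= level) & ~claimed
        piece_labels, n_pieces = ndimage.label(above, structure=struct)
        touching = np.unique(piece_labels[comp])
        for plab in touching[touching > 0]:
            piece = piece_labels == plab
            if vals[piece].max() >= seed_level:
                raw.append(piece)
                claimed |= piece

    # Admission and volume filtering.
    offs = sphere_offsets(volume.spacing, settings.peak_sphere_volume_cm3)
    voxel_cm3 = volume.voxel_volume_mm3 / 1000.0
    kept: list[CandidateROI] = []
    for piece in raw:
        voxels = np.argwhere(piece)
        peak = float(np.max(sphere_mean_at(vals, voxels, offs)))
        if settings.admission_mode == "blood_pool_peak" and not peak > ref_stats.threshold_suvpeak:
            continue
        vol_cm3 = len(voxels) * voxel_cm3
        if vol_cm3 < settings.min_volume_cm3:
            continue
        centroid = tuple(volume.index_to_world(voxels.mean(axis=0)))
        kept.append(
            CandidateROI(
                id=0,
                mask=VoxelMask(piece, volume.spacing, volume.origin),
                suvmax=float(vals[piece].max()),
                suvpeak=peak,
                volume_cm3=vol_cm3,
                centroid_mm=centroid,
            )
        )

    kept.sort(key=lambda c: (-c.suvmax, c.centroid_mm))
    return [c.with_id(i + 1) for i, c in enumerate(kept)]
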
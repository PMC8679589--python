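"""Brute-force reference implementation of multi-foci candidate detection.

Deliberately naive and independent of the library's vectorized code paths:
connected components by breadth-first flood fill over explicit neighbor
lists, sphere means by per-voxel loops. Used only to cross-check
``tmtvkit.mfs.detect_candidates`` on small grids.
"""

import math
from collections import deque

import numpy as np


def neighbor_offsets(connectivity=26):
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dx, dy, dz))
    return offs


def flood_components(mask, connectivity=26):
    """List of voxel-index sets, one per connected component."""
    shape = mask.shape
    seen = np.zeros(shape, dtype=bool)
    offs = neighbor_offsets(connectivity)
    comps = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        comp = set()
        q = deque([start])
        seen[start] = True
        while q:
            v = q.popleft()
            comp.add(v)
            for d in offs:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if all(0 <= w[a] < shape[a] for a in range(3)) and mask[w] and not seen[w]:
                    seen[w] = True
                    q.append(w)
        comps.append(comp)
    return comps


def sphere_offsets_naive(spacing, volume_cm3):
    r = (3.0 * volume_cm3 * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    out = []
    reach = [int(math.floor(r / s)) for s in spacing]
    for dx in range(-reach[0], reach[0] + 1):
        for dy in range(-reach[1], reach[1] + 1):
            for dz in range(-reach[2], reach[2] + 1):
                d2 = (dx * spacing[0]) ** 2 + (dy * spacing[1]) ** 2 + (dz * spacing[2]) ** 2
                if d2 <= r * r:
                    out.append((dx, dy, dz))
    return out


def sphere_mean_naive(values, voxel, offsets):
    shape = values.shape
    acc = []
    for d in offsets:
        w = (voxel[0] + d[0], voxel[1] + d[1], voxel[2] + d[2])
        if all(0 <= w[a] < shape[a] for a in range(3)):
            acc.append(values[w])
    return float(np.mean(acc))


def suv_peak_naive(values, voxels, offsets):
    return max(sphere_mean_naive(values, v, offsets) for v in voxels)


def detect_bruteforce(values, spacing, settings, ref_stats=None):
    """Mirror of the documented seed/refine/admit/filter pipeline.

    Returns a list of dicts sorted like the library output: decreasing SUVmax
    with lexicographic-centroid tie-break.
    """
    conn = settings.connectivity
    if settings.admission_mode == "blood_pool_peak":
        seed_level = ref_stats.threshold_suvpeak
    else:
        seed_level = settings.fixed_suv_threshold

    seeds = flood_components(values >= seed_level, conn)

    def comp_key(comp):
        m = max(values[v] for v in comp)
        vstar = min(v for v in comp if values[v] == m)
        return (-m, vstar)

    seeds.sort(key=comp_key)
    claimed = set()
    raw = []
    for comp in seeds:
        comp = comp - claimed
        if not comp:
            continue
        m = max(values[v] for v in comp)
        level = settings.isocontour_fraction * m
        above = values >= level
        for v in claimed:
            above[v] = False
        pieces = [p for p in flood_components(above, conn) if p & comp]
        for piece in pieces:
            if max(values[v] for v in piece) >= seed_level:
                raw.append(piece)
                claimed |= piece

    offsets = sphere_offsets_naive(spacing, settings.peak_sphere_volume_cm3)
    voxel_cm3 = spacing[0] * spacing[1] * spacing[2] / 1000.0
    kept = []
    for piece in raw:
        peak = suv_peak_naive(values, piece, offsets)
        if settings.admission_mode == "blood_pool_peak" and not peak > ref_stats.threshold_suvpeak:
            continue
        vol = len(piece) * voxel_cm3
        if vol < settings.min_volume_cm3:
            continue
        arr = np.array(sorted(piece))
        centroid = tuple(arr.mean(axis=0) * np.asarray(spacing))
        kept.append(
            {
                "voxels": frozenset(piece),
                "suvmax": max(values[v] for v in piece),
                "suvpeak": peak,
                "volume_cm3": vol,
                "centroid_mm": centroid,
            }
        )
    kept.sort(key=lambda c: (-c["suvmax"], c["centroid_mm"]))
    return kept
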
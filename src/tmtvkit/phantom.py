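"""Synthetic whole-body PET phantoms with known ground truth.

No public whole-body FDG-PET cohort with reference lymphoma segmentations
exists, so every downstream stage is exercised on synthetic phantoms: a body
ellipse containing canonical physiologic high-uptake organs (brain, heart,
kidneys, bladder), additional random physiologic foci (bowel uptake, muscle,
inflammation), tumor lesions of known volume, a blood-pool cylinder in the
descending aorta with realistic statistics (mean SUV ~1.6, SD ~0.5), and
additive Gaussian noise in SUV space.

Lesions and organs are rendered as Gaussian-blurred binary ellipsoids whose
peak is rescaled to the requested SUV; the *true* volume of a lesion is the
volume of its pre-blur binary mask, which makes fractional-SUVmax iso-contour
recovery a meaningful (and imperfect) estimator, as on real images.

The cohort generator draws per-subject lesion load so that a subject carries
on the order of 10 suspicious plus ~14 physiologic high-uptake sources
(~24 detectable regions), with a right-skewed (log-normal) true-TMTV
distribution whose median is a few hundred cm^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import CollisionError
from .survival import SurvivalRecord
from .volume import SUVVolume, VoxelMask, cylinder_mask

# Canonical organ layout, in fractions of the grid extent per axis:
# (site, center_frac, semi_axes_mm, peak_suv)
CANONICAL_ORGANS: list[tuple[str, tuple[float, float, float], tuple[float, float, float], float]] = [
    ("brain", (0.50, 0.50, 0.92), (28.0, 28.0, 24.0), 7.0),
    ("heart", (0.45, 0.50, 0.70), (24.0, 24.0, 24.0), 6.0),
    ("kidney", (0.32, 0.56, 0.52), (14.0, 14.0, 24.0), 5.5),
    ("kidney", (0.68, 0.56, 0.52), (14.0, 14.0, 24.0), 5.5),
    ("bladder", (0.50, 0.50, 0.22), (17.0, 17.0, 17.0), 10.0),
]

#: Descending-aorta blood-pool cylinder center, fractions of grid extent.
AORTA_CENTER_FRAC = (0.54, 0.62, 0.62)


@dataclass(frozen=True)
class BlobSpec:
    """A rendered uptake blob: binary ellipsoid blurred with a Gaussian edge."""

    center_mm: tuple[float, float, float]
    axes_mm: tuple[float, float, float]  # semi-axes
    peak_suv: float
    blur_sigma_mm: float = 3.0

    @classmethod
    def sphere(cls, center_mm, radius_mm: float, peak_suv: float, blur_sigma_mm: float = 3.0):
        return cls(tuple(center_mm), (radius_mm,) * 3, peak_suv, blur_sigma_mm)

    @property
    def volume_mm3(self) -> float:
        a, b, c = self.axes_mm
        return 4.0 / 3.0 * math.pi * a * b * c


@dataclass(frozen=True)
class OrganSpec(BlobSpec):
    site: str = "other"


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic whole-body SUV volume."""

    shape: tuple[int, int, int] = (40, 40, 96)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    background_suv: float = 1.0
    organs: tuple[OrganSpec, ...] = ()
    lesions: tuple[BlobSpec, ...] = ()
    noise_sigma: float = 0.15
    blood_pool_mean: float = 1.6
    blood_pool_sd: float = 0.5
    aorta_center_mm: tuple[float, float, float] | None = None
    seed: int = 0

    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape) * np.asarray(self.spacing)

    def frac_to_mm(self, frac) -> tuple[float, float, float]:
        return tuple((np.asarray(frac) * self.extent_mm()).tolist())

    @property
    def aorta_center(self) -> tuple[float, float, float]:
        if self.aorta_center_mm is not None:
            return self.aorta_center_mm
        return self.frac_to_mm(AORTA_CENTER_FRAC)

    def with_default_organs(self) -> "PhantomSpec":
        organs = tuple(
            OrganSpec(self.frac_to_mm(cf), ax, peak, 4.0, site)
            for site, cf, ax, peak in CANONICAL_ORGANS
        )
        return replace(self, organs=organs)


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom volume."""

    lesion_masks: list[VoxelMask]
    organ_masks: list[tuple[str, VoxelMask]]
    body_mask: VoxelMask
    aorta_center_mm: tuple[float, float, float]
    organ_centers: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    @property
    def lesion_volumes_cm3(self) -> list[float]:
        return [m.volume_cm3 for m in self.lesion_masks]

    @property
    def true_tmtv_cm3(self) -> float:
        return float(sum(self.lesion_volumes_cm3))

    @property
    def lesion_union(self) -> VoxelMask:
        if not self.lesion_masks:
            return VoxelMask.empty_like(self.body_mask)
        data = np.zeros(self.body_mask.shape, dtype=bool)
        for m in self.lesion_masks:
            data |= m.data
        return self.body_mask.like(data)


def _voxel_centers(shape, spacing):
    axes = [np.arange(shape[a]) * spacing[a] for a in range(3)]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _ellipsoid_mask(shape, spacing, center_mm, axes_mm) -> np.ndarray:
    gx, gy, gz = _voxel_centers(shape, spacing)
    q = (
        ((gx - center_mm[0]) / axes_mm[0]) ** 2
        + ((gy - center_mm[1]) / axes_mm[1]) ** 2
        + ((gz - center_mm[2]) / axes_mm[2]) ** 2
    )
    return q <= 1.0


def body_mask_for(spec: PhantomSpec) -> VoxelMask:
    """Elliptic-cylinder body region: 84%/76% of the transaxial extent, 4%-96% axially."""
    ex, ey, ez = spec.extent_mm()
    gx, gy, gz = _voxel_centers(spec.shape, spec.spacing)
    q = ((gx - ex / 2) / (0.42 * ex)) ** 2 + ((gy - ey / 2) / (0.38 * ey)) ** 2
    data = (q <= 1.0) & (gz >= 0.04 * ez) & (gz <= 0.96 * ez)
    return VoxelMask(data, spec.spacing)


def _render_blob(shape, spacing, blob: BlobSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return (binary pre-blur mask, unit-peak rendered field)."""
    binary = _ellipsoid_mask(shape, spacing, blob.center_mm, blob.axes_mm)
    if not binary.any():
        # sub-voxel blob: light up the nearest voxel so the spec is never silently lost
        idx = tuple(
            int(np.clip(round(blob.center_mm[a] / spacing[a]), 0, shape[a] - 1)) for a in range(3)
        )
        binary = np.zeros(shape, dtype=bool)
        binary[idx] = True
    if blob.blur_sigma_mm > 0:
        sig = [blob.blur_sigma_mm / spacing[a] for a in range(3)]
        rendered = gaussian_filter(binary.astype(np.float64), sig)
        rendered /= rendered.max()
    else:
        rendered = binary.astype(np.float64)
    return binary, rendered


def generate_phantom(spec: PhantomSpec) -> tuple[SUVVolume, PhantomTruth]:
    """Render one phantom; bit-deterministic for a fixed spec (seed included).

    Raises
    ------
    CollisionError
        If two lesion specifications overlap (their pre-blur masks intersect);
        ground-truth volumes must stay additive.
    """
    rng = np.random.default_rng(spec.seed)
    body = body_mask_for(spec)
    values = np.where(body.data, spec.background_suv, 0.0)

    organ_masks: list[tuple[str, VoxelMask]] = []
    organ_centers: dict[str, tuple[float, float, float]] = {}
    for organ in spec.organs:
        binary, rendered = _render_blob(spec.shape, spec.spacing, organ)
        values += (organ.peak_suv - spec.background_suv) * rendered
        organ_masks.append((organ.site, body.like(binary)))
        organ_centers.setdefault(organ.site, tuple(organ.center_mm))

    lesion_masks: list[VoxelMask] = []
    occupied = np.zeros(spec.shape, dtype=bool)
    for i, lesion in enumerate(spec.lesions):
        binary, rendered = _render_blob(spec.shape, spec.spacing, lesion)
        if (binary & occupied).any():
            raise CollisionError(f"lesion {i} overlaps a previously placed lesion")
        occupied |= binary
        values += (lesion.peak_suv - spec.background_suv) * rendered
        lesion_masks.append(body.like(binary))

    # Blood pool: replace values in the aortic cylinder so that, after global
    # noise is added, the region's SD lands near the configured blood-pool SD.
    vol_tmp = SUVVolume(np.maximum(values, 0.0), spec.spacing)
    cyl = cylinder_mask(vol_tmp, spec.aorta_center, 10.0, 20.0)
    local_sd = math.sqrt(max(spec.blood_pool_sd**2 - spec.noise_sigma**2, 0.0))
    draw = rng.normal(size=cyl.n_voxels)
    if cyl.n_voxels > 1 and draw.std() > 0:
        # standardize the sample so the region's *empirical* statistics match
        # the configured blood-pool mean/SD (the region holds only ~20 voxels,
        # where a raw i.i.d. draw would scatter widely around the target SD)
        draw = (draw - draw.mean()) / draw.std()
    values[cyl.data] = spec.blood_pool_mean + local_sd * draw

    if spec.noise_sigma > 0:
        values = values + rng.normal(0.0, spec.noise_sigma, spec.shape)
    values = np.maximum(values, 0.0)

    truth = PhantomTruth(
        lesion_masks=lesion_masks,
        organ_masks=organ_masks,
        body_mask=body,
        aorta_center_mm=tuple(spec.aorta_center),
        organ_centers=organ_centers,
    )
    return SUVVolume(values, spec.spacing), truth


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalModelSpec:
    """Proportional-hazards outcome simulator parameters.

    Event times are exponential with hazard ``h0 * exp(beta * x)`` where
    ``x`` is either the high-TMTV group indicator (``covariate="group"``,
    TMTV above ``cutoff_cm3``) or standardized ``log(TMTV + 1)``
    (``covariate="log"``); ``beta = log(hazard_ratio)``. Follow-up is
    administratively censored at ``censor_time_years``.
    """

    baseline_hazard_per_year: float = 0.1
    hazard_ratio: float = 2.5
    cutoff_cm3: float = 240.0
    covariate: str = "group"
    censor_time_years: float = 8.0

    def __post_init__(self) -> None:
        if not self.baseline_hazard_per_year > 0:
            raise ValueError("baseline hazard must be > 0")
        if self.covariate not in ("group", "log"):
            raise ValueError(f"unknown covariate type {self.covariate!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level generative parameters.

    Defaults target the detection load and TMTV scale of a whole-body DLBCL
    cohort: ~10 tumor lesions plus ~14 physiologic candidate sources per
    subject (5 canonical organs + ~9 random foci), and a log-normal true-TMTV
    distribution with median ~240 cm^3.
    """

    n_subjects: int = 50
    mean_lesions: float = 10.0
    mean_physio_foci: float = 12.0
    tmtv_median_cm3: float = 240.0
    tmtv_log_sigma: float = 0.9
    lesion_peak_suv: tuple[float, float] = (6.5, 12.0)
    focus_peak_suv: tuple[float, float] = (5.0, 6.3)
    focus_volume_cm3: tuple[float, float] = (1.4, 0.5)  # log-normal median, sigma
    phantom: PhantomSpec = PhantomSpec()
    survival: SurvivalModelSpec = SurvivalModelSpec()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")


def _sample_position(rng, spec: PhantomSpec, radius_mm, placed, organs, aorta, max_tries=400):
    """Rejection-sample a blob center inside the body, away from other blobs."""
    ex, ey, ez = spec.extent_mm()
    ax, ay = 0.42 * ex, 0.38 * ey
    for _ in range(max_tries):
        u, v = rng.uniform(-1, 1, 2)
        if u * u + v * v > 1:
            continue
        margin = radius_mm + 3.0
        x = ex / 2 + u * max(ax - margin, 1.0)
        y = ey / 2 + v * max(ay - margin, 1.0)
        z = rng.uniform(0.06 * ez + radius_mm, 0.94 * ez - radius_mm)
        p = np.array([x, y, z])
        ok = True
        for c, r in placed:
            if np.linalg.norm(p - c) < radius_mm + r + 3.0:
                ok = False
                break
        if ok:
            for c, r in organs:
                if np.linalg.norm(p - c) < radius_mm + r + 3.0:
                    ok = False
                    break
        if ok and np.linalg.norm(p[:2] - np.asarray(aorta)[:2]) < radius_mm + 14.0:
            ok = False
        if ok:
            return p
    return None


def sample_subject_spec(cohort: CohortSpec, rng: np.random.Generator, seed: int) -> PhantomSpec:
    """Draw one subject's phantom specification from the cohort distributions."""
    base = cohort.phantom.with_default_organs()
    organs = list(base.organs)
    organ_keepout = [(np.asarray(o.center_mm), max(o.axes_mm)) for o in organs]
    aorta = base.aorta_center
    placed: list[tuple[np.ndarray, float]] = []

    lesions: list[BlobSpec] = []
    n_les = int(rng.poisson(cohort.mean_lesions))
    if n_les > 0:
        target = rng.lognormal(math.log(cohort.tmtv_median_cm3), cohort.tmtv_log_sigma)
        weights = np.sort(rng.dirichlet(np.ones(n_les)))[::-1]  # place large lesions first
        for w in weights:
            vol_mm3 = max(w * target, 0.05) * 1000.0
            radius = max((3.0 * vol_mm3 / (4.0 * math.pi)) ** (1.0 / 3.0), 4.0)
            pos = _sample_position(rng, base, radius, placed, organ_keepout, aorta)
            if pos is None:
                continue
            placed.append((pos, radius))
            peak = rng.uniform(*cohort.lesion_peak_suv)
            lesions.append(BlobSpec.sphere(tuple(pos), radius, peak))

    n_foci = int(rng.poisson(cohort.mean_physio_foci))
    for _ in range(n_foci):
        vol_cm3 = rng.lognormal(math.log(cohort.focus_volume_cm3[0] * 3.0), cohort.focus_volume_cm3[1])
        radius = max((3.0 * vol_cm3 * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0), 4.0)
        # physiologic foci (bowel loops, muscle bands, inflammation) are
        # elongated and of moderate intensity, unlike the rounder, hotter tumors
        elong = rng.uniform(2.0, 3.0)
        a = radius / elong ** (1.0 / 3.0)
        axes = [a, a, a]
        axes[int(rng.integers(3))] = a * elong
        keepout = max(axes)
        pos = _sample_position(rng, base, keepout, placed, organ_keepout, aorta)
        if pos is None:
            continue
        placed.append((pos, keepout))
        peak = rng.uniform(*cohort.focus_peak_suv)
        site = str(rng.choice(["bowel", "other"]))
        organs.append(OrganSpec(tuple(pos), tuple(axes), peak, 3.0, site))

    return replace(base, organs=tuple(organs), lesions=tuple(lesions), seed=seed)


def generate_cohort(cohort: CohortSpec) -> list[tuple[SUVVolume, PhantomTruth]]:
    """Generate ``n_subjects`` phantoms; deterministic for a fixed cohort seed."""
    ss = np.random.SeedSequence(cohort.seed)
    out = []
    for child in ss.spawn(cohort.n_subjects):
        rng = np.random.default_rng(child)
        subject_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        spec = sample_subject_spec(cohort, rng, subject_seed)
        out.append(generate_phantom(spec))
    return out


def simulate_survival(
    tmtv_values_cm3,
    model: SurvivalModelSpec,
    seed: int = 0,
    subject_ids=None,
) -> list[SurvivalRecord]:
    """Draw right-censored proportional-hazards outcomes linked to TMTV."""
    tmtv = np.asarray(tmtv_values_cm3, dtype=float)
    if np.any(tmtv < 0):
        raise ValueError("TMTV values must be >= 0")
    rng = np.random.default_rng(seed)
    beta = math.log(model.hazard_ratio)
    if model.covariate == "group":
        x = (tmtv > model.cutoff_cm3).astype(float)
    else:
        logs = np.log1p(tmtv)
        sd = logs.std()
        x = (logs - logs.mean()) / sd if sd > 0 else np.zeros_like(logs)
    hazard = model.baseline_hazard_per_year * np.exp(beta * x)
    t_event = rng.exponential(1.0 / hazard)
    time = np.minimum(t_event, model.censor_time_years)
    event = (t_event <= model.censor_time_years).astype(int)
    if subject_ids is None:
        subject_ids = [f"S{i:04d}" for i in range(len(tmtv))]
    return [
        SurvivalRecord(subject_id=sid, time_years=float(t), event=int(e), tmtv_cm3=float(v))
        for sid, t, e, v in zip(subject_ids, time, event, tmtv)
    ]
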
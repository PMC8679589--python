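"""Physiologic-vs-suspicious classification of candidate ROIs.

On real images this decision is made by a trained deep network; that network
(architecture, weights, training data) is not reproducible and is therefore
replaced here by a classifier *contract* plus two implementations:

* :class:`OracleClassifier` — labels each candidate from the synthetic ground
  truth (suspicious iff at least half of its voxels lie inside the true
  lesion union), used to test every downstream stage in isolation;
* :class:`BaselineClassifier` — a regularized logistic regression on
  hand-crafted ROI features (intensity, volume, shape, position relative to
  the canonical organs), trained against oracle labels.

User classifiers can be registered by name via :func:`register_classifier`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from skimage import measure
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .errors import DegenerateDataError, EmptyRegionError, GridMismatchError
from .mfs import CandidateROI
from .phantom import CANONICAL_ORGANS, PhantomTruth
from .volume import SUVVolume, VoxelMask


class UptakeClass(str, Enum):
    PHYSIOLOGIC = "physiologic"
    SUSPICIOUS = "suspicious"


class AnatomicalSite(str, Enum):
    BRAIN = "brain"
    HEART = "heart"
    BLADDER = "bladder"
    KIDNEY = "kidney"
    BOWEL = "bowel"
    NODAL = "nodal"
    EXTRANODAL = "extranodal"
    OTHER = "other"


DEFAULT_DECISION_THRESHOLD = 0.5


@dataclass
class ClassifiedROI:
    """A candidate ROI with its uptake class, anatomic site and score.

    ``score`` is the suspicion score in [0, 1]; the class is suspicious iff
    ``score >= threshold`` (0.5 by default).
    """

    roi: CandidateROI
    uptake_class: UptakeClass
    site: AnatomicalSite
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must be in [0, 1], got {self.score}")

    @property
    def is_suspicious(self) -> bool:
        return self.uptake_class is UptakeClass.SUSPICIOUS

    @property
    def volume_cm3(self) -> float:
        return self.roi.volume_cm3


@dataclass
class SubjectContext:
    """Everything a classifier may consult about one subject."""

    volume: SUVVolume
    body_mask: VoxelMask | None = None
    truth: PhantomTruth | None = None


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROIFeatures:
    """Hand-crafted per-ROI feature vector (deep-network input stand-in)."""

    suvmax: float
    suvpeak: float
    volume_cm3: float
    centroid_frac: tuple[float, float, float]  # position within the body bbox
    sphericity: float
    organ_distances_mm: tuple[float, ...]  # to each canonical organ center

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.suvmax, self.suvpeak, self.volume_cm3, *self.centroid_frac,
             self.sphericity, *self.organ_distances_mm]
        )

    @staticmethod
    def names() -> list[str]:
        organs = [f"dist_{site}_{i}" for i, (site, *_rest) in enumerate(CANONICAL_ORGANS)]
        return ["suvmax", "suvpeak", "volume_cm3", "cx", "cy", "cz", "sphericity", *organs]


def _surface_area_mm2(mask: VoxelMask) -> float:
    """Mesh surface area of a voxel mask (marching cubes at the 0.5 level)."""
    padded = np.pad(mask.data.astype(np.float64), 1)
    verts, faces, *_ = measure.marching_cubes(padded, level=0.5, spacing=mask.spacing)
    return float(measure.mesh_surface_area(verts, faces))


def sphericity(mask: VoxelMask) -> float:
    """pi^(1/3) (6V)^(2/3) / A, clipped into (0, 1] (discrete surfaces can
    slightly under-measure A for near-spherical shapes)."""
    if mask.n_voxels == 0:
        raise EmptyRegionError("sphericity of an empty mask")
    v_mm3 = mask.n_voxels * mask.voxel_volume_mm3
    a = _surface_area_mm2(mask)
    return float(min(np.pi ** (1.0 / 3.0) * (6.0 * v_mm3) ** (2.0 / 3.0) / a, 1.0))


def canonical_organ_centers_mm(volume: SUVVolume) -> list[tuple[str, np.ndarray]]:
    extent = np.asarray(volume.shape) * np.asarray(volume.spacing)
    return [(site, np.asarray(cf) * extent) for site, cf, _ax, _peak in CANONICAL_ORGANS]


def extract_features(
    roi: CandidateROI, volume: SUVVolume, body_mask: VoxelMask
) -> ROIFeatures:
    """Deterministic feature vector for one candidate ROI."""
    if body_mask is None or body_mask.n_voxels == 0:
        raise EmptyRegionError("feature extraction requires a non-empty body mask")
    body_idx = np.argwhere(body_mask.data)
    lo = volume.index_to_world(body_idx.min(axis=0))
    hi = volume.index_to_world(body_idx.max(axis=0))
    span = np.maximum(hi - lo, 1e-9)
    centroid = np.asarray(roi.centroid_mm)
    frac = tuple(((centroid - lo) / span).tolist())
    dists = tuple(
        float(np.linalg.norm(centroid - c)) for _site, c in canonical_organ_centers_mm(volume)
    )
    return ROIFeatures(
        suvmax=roi.suvmax,
        suvpeak=roi.suvpeak,
        volume_cm3=roi.volume_cm3,
        centroid_frac=frac,
        sphericity=sphericity(roi.mask),
        organ_distances_mm=dists,
    )


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

def overlap_fraction(roi_mask: VoxelMask, reference: VoxelMask) -> float:
    """|roi ∩ reference| / |roi|."""
    if roi_mask.shape != reference.shape:
        raise GridMismatchError("ROI and reference mask are on different grids")
    n = roi_mask.n_voxels
    if n == 0:
        raise EmptyRegionError("overlap of an empty ROI")
    return float((roi_mask.data & reference.data).sum() / n)


class OracleClassifier:
    """Ground-truth classifier: suspicious iff the ROI overlaps the true
    lesion union by at least ``overlap_rule`` of its volume; scores in {0, 1}.

    Site assignment: suspicious ROIs are ``nodal``; physiologic ROIs take the
    site of the organ they overlap most (falling back to the nearest labeled
    organ center, then ``other``).
    """

    name = "oracle"

    def __init__(self, overlap_rule: float = 0.5):
        self.overlap_rule = overlap_rule

    def classify(self, rois, context: SubjectContext) -> list[ClassifiedROI]:
        truth = context.truth
        if truth is None:
            raise ValueError("oracle classifier requires ground truth in the context")
        union = truth.lesion_union
        out = []
        for roi in rois:
            frac = overlap_fraction(roi.mask, union)
            if frac >= self.overlap_rule:
                out.append(ClassifiedROI(roi, UptakeClass.SUSPICIOUS, AnatomicalSite.NODAL, 1.0))
                continue
            site = self._physiologic_site(roi, truth)
            out.append(ClassifiedROI(roi, UptakeClass.PHYSIOLOGIC, site, 0.0))
        return out

    @staticmethod
    def _physiologic_site(roi: CandidateROI, truth: PhantomTruth) -> AnatomicalSite:
        best_site, best_overlap = None, 0
        for site, mask in truth.organ_masks:
            ov = int((roi.mask.data & mask.data).sum())
            if ov > best_overlap:
                best_site, best_overlap = site, ov
        if best_site is None and truth.organ_centers:
            centroid = np.asarray(roi.centroid_mm)
            best_site = min(
                truth.organ_centers.items(),
                key=lambda kv: float(np.linalg.norm(centroid - np.asarray(kv[1]))),
            )[0]
        try:
            return AnatomicalSite(best_site)
        except ValueError:
            return AnatomicalSite.OTHER


class BaselineClassifier:
    """Regularized logistic regression on standardized ROI features."""

    name = "baseline"
    version = 1

    def __init__(self, decision_threshold: float = DEFAULT_DECISION_THRESHOLD, seed: int = 0):
        self.decision_threshold = decision_threshold
        self.seed = seed
        self._pipe = make_pipeline(
            StandardScaler(), LogisticRegression(C=10.0, max_iter=2000, random_state=seed)
        )
        self.holdout_accuracy: float | None = None

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "BaselineClassifier":
        labels = np.asarray(labels, dtype=int)
        if len(np.unique(labels)) < 2:
            raise DegenerateDataError("training labels contain a single class")
        self._pipe.fit(np.asarray(features, dtype=float), labels)
        return self

    def predict_score(self, features: np.ndarray) -> np.ndarray:
        """Suspicion probability per row."""
        return self._pipe.predict_proba(np.asarray(features, dtype=float))[:, 1]

    def classify(self, rois, context: SubjectContext) -> list[ClassifiedROI]:
        if not rois:
            return []
        body = context.body_mask
        if body is None and context.truth is not None:
            body = context.truth.body_mask
        feats = np.stack(
            [extract_features(r, context.volume, body).to_array() for r in rois]
        )
        scores = self.predict_score(feats)
        out = []
        for roi, score in zip(rois, scores):
            suspicious = score >= self.decision_threshold
            cls = UptakeClass.SUSPICIOUS if suspicious else UptakeClass.PHYSIOLOGIC
            site = AnatomicalSite.NODAL if suspicious else AnatomicalSite.OTHER
            out.append(ClassifiedROI(roi, cls, site, float(score)))
        return out

    # -- serialization (versioned, with standardization constants) ----------
    def to_dict(self) -> dict:
        scaler: StandardScaler = self._pipe.named_steps["standardscaler"]
        lr: LogisticRegression = self._pipe.named_steps["logisticregression"]
        return {
            "format_version": self.version,
            "decision_threshold": self.decision_threshold,
            "feature_names": ROIFeatures.names(),
            "feature_mean": scaler.mean_.tolist(),
            "feature_scale": scaler.scale_.tolist(),
            "coef": lr.coef_.tolist(),
            "intercept": lr.intercept_.tolist(),
            "classes": lr.classes_.tolist(),
            "holdout_accuracy": self.holdout_accuracy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BaselineClassifier":
        if d.get("format_version") != cls.version:
            raise ValueError(f"unsupported classifier file version {d.get('format_version')}")
        obj = cls(decision_threshold=d["decision_threshold"])
        scaler = StandardScaler()
        scaler.mean_ = np.asarray(d["feature_mean"])
        scaler.scale_ = np.asarray(d["feature_scale"])
        scaler.var_ = scaler.scale_ ** 2
        scaler.n_features_in_ = len(scaler.mean_)
        lr = LogisticRegression()
        lr.coef_ = np.asarray(d["coef"])
        lr.intercept_ = np.asarray(d["intercept"])
        lr.classes_ = np.asarray(d["classes"])
        obj._pipe = make_pipeline(scaler, lr)
        obj.holdout_accuracy = d.get("holdout_accuracy")
        return obj


def train_baseline(
    features: np.ndarray,
    labels,
    seed: int = 0,
    test_fraction: float = 0.33,
    decision_threshold: float = DEFAULT_DECISION_THRESHOLD,
) -> BaselineClassifier:
    """Train the baseline on features + (oracle) labels; records held-out accuracy."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise DegenerateDataError("training labels contain a single class")
    x_tr, x_te, y_tr, y_te = train_test_split(
        features, labels, test_size=test_fraction, random_state=seed, stratify=labels
    )
    clf = BaselineClassifier(decision_threshold=decision_threshold, seed=seed).fit(x_tr, y_tr)
    pred = (clf.predict_score(x_te) >= decision_threshold).astype(int)
    clf.holdout_accuracy = float(np.mean(pred == y_te))
    return clf


def classify_subject(rois, classifier, context: SubjectContext) -> list[ClassifiedROI]:
    """Apply any classifier to a candidate list; order is preserved, every
    candidate receives exactly one class/site/score."""
    out = classifier.classify(list(rois), context)
    if len(out) != len(rois):
        raise RuntimeError("classifier must return one ClassifiedROI per candidate")
    return out


# -- plug-in registry --------------------------------------------------------

_REGISTRY: dict[str, type] = {"oracle": OracleClassifier, "baseline": BaselineClassifier}


def register_classifier(name: str, factory) -> None:
    _REGISTRY[name] = factory


def get_classifier(name: str, **kwargs):
    try:
        return _REGISTRY[name](**kwargs)
    except KeyError:
        raise KeyError(f"no classifier registered under {name!r}") from None
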
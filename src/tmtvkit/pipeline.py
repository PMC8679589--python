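"""End-to-end per-subject and cohort processing.

``process_subject`` chains the stages: blood-pool reference statistics,
multi-foci candidate detection, uptake classification, TMTV aggregation.
``evaluate_cohort`` runs the evaluation layer over processed subjects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .blood_pool import ReferenceStats, blood_pool_stats
from .classify import SubjectContext, classify_subject
from .errors import EmptyRegionError
from .evaluation import (
    AgreementReport,
    bland_altman,
    confusion_metrics,
    match_rois,
    spearman_rho,
    voxel_agreement,
)
from .mfs import SegmentationSettings, detect_candidates
from .phantom import PhantomTruth
from .tmtv import SubjectResult, compute_tmtv
from .volume import SUVVolume, VoxelMask


def process_subject(
    subject_id: str,
    volume: SUVVolume,
    settings: SegmentationSettings,
    classifier,
    aorta_center_mm=None,
    truth: PhantomTruth | None = None,
    body_mask: VoxelMask | None = None,
    ref_stats: ReferenceStats | None = None,
    settings_name: str = "custom",
) -> SubjectResult:
    """Run detection + classification + TMTV for one subject.

    The blood-pool reference is computed from ``aorta_center_mm`` (or the
    truth's aorta center) unless ``ref_stats`` is supplied directly.
    """
    if ref_stats is None and settings.admission_mode == "blood_pool_peak":
        center = aorta_center_mm
        if center is None and truth is not None:
            center = truth.aorta_center_mm
        if center is None:
            raise ValueError("blood_pool_peak mode needs an aorta center or explicit stats")
        ref_stats = blood_pool_stats(volume, center)

    candidates = detect_candidates(volume, ref_stats, settings)
    context = SubjectContext(
        volume=volume,
        body_mask=body_mask if body_mask is not None else (truth.body_mask if truth else None),
        truth=truth,
    )
    classified = classify_subject(candidates, classifier, context)
    bp = (
        {"mean_suv": ref_stats.mean_suv, "sd_suv": ref_stats.sd_suv,
         "threshold_suvpeak": ref_stats.threshold_suvpeak}
        if ref_stats is not None
        else {}
    )
    return SubjectResult(
        subject_id=subject_id,
        settings_name=settings_name,
        rois=classified,
        tmtv_cm3=compute_tmtv(classified),
        ref_union=truth.lesion_union if truth is not None else None,
        true_tmtv_cm3=truth.true_tmtv_cm3 if truth is not None else None,
        blood_pool=bp,
    )


def tmtv_table(results: list[SubjectResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "setting": r.settings_name,
                "tmtv_cm3": r.tmtv_cm3,
                "n_rois": r.n_rois,
                "n_suspicious": r.n_suspicious,
                "true_tmtv_cm3": r.true_tmtv_cm3,
            }
            for r in results
        ]
    )


def candidate_table(result: SubjectResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": result.subject_id,
                "setting": result.settings_name,
                "roi_id": c.roi.id,
                "suvmax": c.roi.suvmax,
                "suvpeak": c.roi.suvpeak,
                "volume_cm3": c.roi.volume_cm3,
                "centroid_x_mm": c.roi.centroid_mm[0],
                "centroid_y_mm": c.roi.centroid_mm[1],
                "centroid_z_mm": c.roi.centroid_mm[2],
                "uptake_class": c.uptake_class.value,
                "site": c.site.value,
                "score": c.score,
            }
            for c in result.rois
        ]
    )


def label_map(result: SubjectResult) -> VoxelMask | None:
    """Candidate label image (voxel value = candidate id), as a uint8-ready array."""
    if not result.rois:
        return None
    first = result.rois[0].roi.mask
    lab = np.zeros(first.shape, dtype=np.int32)
    for c in result.rois:
        lab[c.roi.mask.data] = c.roi.id
    return lab


def evaluate_cohort(
    results: list[SubjectResult],
    rule: float = 0.50,
    rules=(0.25, 0.50, 0.75),
) -> dict:
    """Cohort evaluation against each subject's reference union.

    Returns confusion reports at every requested rule, the voxel-agreement
    report, Bland-Altman limits and the Spearman correlation between the
    pipeline TMTV and the reference-union volume.
    """
    matches_by_subject = []
    agreement = AgreementReport(dice=[], precision=[], recall=[])
    tmtv_pairs = []
    for r in results:
        if r.ref_union is None:
            raise EmptyRegionError(f"subject {r.subject_id} has no reference union")
        matches_by_subject.append(match_rois(r.rois, r.ref_union, min_overlap=rule, rules=rules))
        susp = r.suspicious_union
        if susp is None:
            susp = VoxelMask.empty_like(r.ref_union)
        dice, prec, rec = voxel_agreement(susp, r.ref_union)
        agreement.dice.append(dice)
        agreement.precision.append(prec)
        agreement.recall.append(rec)
        tmtv_pairs.append((r.tmtv_cm3, r.ref_union.volume_cm3))

    reports = {f"rule_{q:g}": confusion_metrics(matches_by_subject, rule=q) for q in rules}
    pairs = np.asarray(tmtv_pairs)
    if len(pairs) >= 3:
        agreement.bland_altman = bland_altman(pairs)
        try:
            rho, p = spearman_rho(pairs[:, 0], pairs[:, 1])
            agreement.spearman_rho, agreement.spearman_p = rho, p
        except Exception:
            pass  # degenerate cohorts (e.g. all-zero TMTV) simply omit rho
    return {"confusion": reports, "agreement": agreement, "tmtv_pairs": pairs}
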
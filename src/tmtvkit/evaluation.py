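"""Evaluation of the uptake classification and TMTV agreement.

Three layers of comparison against a per-subject reference lesion union:

* **ROI-level matching** — a candidate matches the reference if at least a
  fixed fraction of its voxels (50% by default; 25% and 75% as alternate
  rules) lie inside the union of reference lesions. Crossing suspicious /
  physiologic with matched / unmatched yields TP, FN, TN, FP and the derived
  sensitivity, specificity and accuracy.
* **Voxel-level agreement** — Dice, precision and recall between the union of
  suspicious candidates and the reference union.
* **TMTV agreement** — Spearman rank correlation and Bland-Altman analysis
  with a median bias and empirical 2.5/97.5-percentile limits of agreement
  (linear-interpolation quantile definition).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .classify import ClassifiedROI
from .errors import (
    DegenerateDataError,
    GridMismatchError,
    InsufficientDataError,
    UndefinedStatisticError,
)
from .volume import VoxelMask

STANDARD_OVERLAP_RULES = (0.25, 0.50, 0.75)


# ---------------------------------------------------------------------------
# ROI matching and confusion metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatchResult:
    """Overlap of one classified ROI with the reference union."""

    roi_id: int
    suspicious: bool
    overlap_fraction: float
    matched: dict  # rule -> bool, inclusive ("at least") at each rule
    confusion: str  # TP/FP/TN/FN at the requested rule

    def confusion_at(self, rule: float) -> str:
        m = self.matched[rule]
        if self.suspicious:
            return "TP" if m else "FP"
        return "FN" if m else "TN"


def match_rois(
    classified: list[ClassifiedROI],
    ref_union: VoxelMask,
    min_overlap: float = 0.50,
    rules=STANDARD_OVERLAP_RULES,
) -> list[MatchResult]:
    """Match every classified ROI against the reference union.

    ``matched`` is inclusive: an overlap of exactly the rule value counts.
    """
    rules = tuple(sorted(set(rules) | {min_overlap}))
    out = []
    for c in classified:
        if c.roi.mask.shape != ref_union.shape:
            raise GridMismatchError("ROI and reference union are on different grids")
        n = c.roi.mask.n_voxels
        frac = float((c.roi.mask.data & ref_union.data).sum() / n) if n else 0.0
        matched = {r: frac >= r for r in rules}
        m = MatchResult(
            roi_id=c.roi.id,
            suspicious=c.is_suspicious,
            overlap_fraction=frac,
            matched=matched,
            confusion="",
        )
        out.append(
            MatchResult(m.roi_id, m.suspicious, m.overlap_fraction, matched, m.confusion_at(min_overlap))
        )
    return out


@dataclass
class ConfusionReport:
    """Cohort confusion counts and rates for the uptake classification."""

    tp: int
    fp: int
    tn: int
    fn: int
    per_subject_accuracy: list[float] = field(default_factory=list)
    sensitivity_defined: bool = True
    specificity_defined: bool = True

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int) -> "ConfusionReport":
        if min(tp, fp, tn, fn) < 0 or tp + fp + tn + fn == 0:
            raise DegenerateDataError("confusion counts must be non-negative with total >= 1")
        return cls(tp, fp, tn, fn,
                   sensitivity_defined=tp + fn > 0, specificity_defined=tn + fp > 0)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        if not self.sensitivity_defined:
            raise UndefinedStatisticError("sensitivity undefined: no matched ROIs")
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        if not self.specificity_defined:
            raise UndefinedStatisticError("specificity undefined: no unmatched ROIs")
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def suspicious_fraction(self) -> float:
        """Fraction of all ROIs labeled suspicious: (TP + FP) / total."""
        return (self.tp + self.fp) / self.total

    def rounded_percent(self) -> dict:
        """Display rounding to the nearest integer percent."""
        out = {"accuracy": round(100 * self.accuracy)}
        if self.sensitivity_defined:
            out["sensitivity"] = round(100 * self.sensitivity)
        if self.specificity_defined:
            out["specificity"] = round(100 * self.specificity)
        out["suspicious_fraction"] = round(100 * self.suspicious_fraction)
        return out

    def per_subject_summary(self) -> dict:
        if not self.per_subject_accuracy:
            return {}
        acc = np.asarray(self.per_subject_accuracy)
        q1, med, q3 = np.percentile(acc, [25, 50, 75])
        return {"mean": float(acc.mean()), "median": float(med), "iqr": (float(q1), float(q3))}


def confusion_metrics(
    matches_by_subject: list[list[MatchResult]], rule: float = 0.50
) -> ConfusionReport:
    """Aggregate confusion counts over subjects at one overlap rule."""
    counts = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    per_subject = []
    for matches in matches_by_subject:
        sub = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
        for m in matches:
            sub[m.confusion_at(rule)] += 1
        for k in counts:
            counts[k] += sub[k]
        n = sum(sub.values())
        if n:
            per_subject.append((sub["TP"] + sub["TN"]) / n)
    if sum(counts.values()) == 0:
        raise DegenerateDataError("no ROIs to evaluate")
    rep = ConfusionReport.from_counts(counts["TP"], counts["FP"], counts["TN"], counts["FN"])
    rep.per_subject_accuracy = per_subject
    return rep


# ---------------------------------------------------------------------------
# Voxel-level agreement
# ---------------------------------------------------------------------------

def voxel_agreement(
    suspicious_union: VoxelMask, ref_union: VoxelMask
) -> tuple[float, float, float]:
    """(Dice, precision, recall) between two voxel sets.

    Conventions for empty sets: both empty -> (1, 1, 1); exactly one empty ->
    (0, 0, 0) for the affected metrics.
    """
    if suspicious_union.shape != ref_union.shape:
        raise GridMismatchError("masks on different grids")
    a = suspicious_union.data
    b = ref_union.data
    na, nb = int(a.sum()), int(b.sum())
    inter = int((a & b).sum())
    if na == 0 and nb == 0:
        return 1.0, 1.0, 1.0
    dice = 2.0 * inter / (na + nb)
    precision = inter / na if na else 0.0
    recall = inter / nb if nb else 0.0
    return dice, precision, recall


@dataclass
class AgreementReport:
    """Cohort voxel-agreement and TMTV-agreement summary."""

    dice: list[float]
    precision: list[float]
    recall: list[float]
    spearman_rho: float | None = None
    spearman_p: float | None = None
    bland_altman: tuple[float, float, float] | None = None

    def median_iqr(self, name: str) -> dict:
        vals = np.asarray(getattr(self, name))
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        return {"median": float(med), "iqr": (float(q1), float(q3))}


# ---------------------------------------------------------------------------
# TMTV agreement statistics
# ---------------------------------------------------------------------------

def bland_altman(pairs) -> tuple[float, float, float]:
    """Median bias and 2.5/97.5-percentile limits of agreement of a - b.

    Limits use the linear-interpolation quantile definition (numpy default),
    i.e. interpolation between order statistics at position (n-1)q.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise InsufficientDataError("Bland-Altman needs at least 3 (a, b) pairs")
    d = arr[:, 0] - arr[:, 1]
    lo, hi = np.percentile(d, [2.5, 97.5])
    return float(np.median(d)), float(lo), float(hi)


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The p-value uses the t approximation for n > 10 and the exact permutation
    distribution (all n! permutations, two-sided) for n <= 10.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise InsufficientDataError("spearman_rho needs two equal-length vectors, n >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise UndefinedStatisticError("zero rank variance: correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    if n > 10:
        t = rho * math.sqrt((n - 2) / max(1.0 - rho * rho, 1e-300))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    else:
        obs = abs(rho)
        count, total = 0, 0
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        denom = math.sqrt(float(np.sum(rx_c**2) * np.sum(ry_c**2)))
        for perm in itertools.permutations(range(n)):
            r = float(np.dot(rx_c, ry_c[list(perm)])) / denom
            total += 1
            if abs(r) >= obs - 1e-12:
                count += 1
        p = count / total
    return rho, float(min(p, 1.0))
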
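# Methods

`tmtvkit` implements a fully automated estimator of total metabolic tumor
volume (TMTV) on whole-body ¹⁸F-FDG PET, together with the machinery needed
to validate it: a synthetic phantom cohort with known ground truth, an
evaluation layer for the uptake classification, and a prognostic survival
layer. This note records the models, the parameters that matter, the
numerical conventions, and what the synthetic experiments do and do not show.

## SUV volumes and geometry

All image operations act on `SUVVolume`: a 3-D array of standardized uptake
values (dimensionless, g/mL convention) on a regular grid with per-axis
spacing in millimetres, axis order (x, y, z) with z cranio-caudal. Voxel
indices are 0-based; the world position of voxel (i, j, k) is
`origin + index * spacing`, i.e. the voxel center. A voxel belongs to a
geometric region (sphere, cylinder, ellipsoid) iff its center lies inside —
a single deterministic rule that makes every mask bit-reproducible, at the
cost of a small quantization error in realized volumes (which shrinks as
spacing decreases; tested at 2/1/0.5 mm).

SUV conversion from an activity-concentration map uses
`SUV = conc / (decayed_dose / body_weight)` with base-2 decay over the
uptake interval and the ¹⁸F half-life 109.77 min as default. Vendors differ
in their decay conventions; this one is the common textbook definition and
is stated so results are reproducible.

## Candidate detection (multi-foci segmentation)

Detection follows PERCIST-style practice:

1. **Reference region.** A 10 mm × 20 mm cylinder at the center of the
   proximal descending aorta provides the blood-pool mean SUV and its
   population SD (ddof = 0; a deterministic choice). The admission threshold
   is `2·mean + 2·SD`. Cylinder dimensions are configurable; the defaults
   follow common PERCIST usage. Automatic aorta localization is out of
   scope: the center comes from ground truth or user configuration.
2. **Seeds.** Connected components (26-neighborhood, configurable) of voxels
   at or above the seed level — the blood-pool threshold, or a fixed SUV of
   2.5 in the alternative presets.
3. **Iso-contour refinement.** Each seed component is re-thresholded at a
   fraction (42% default, 41% in the alternative presets) of its own SUVmax
   (region-wise, not global). The refined candidate is the connected
   component containing the maximizing voxel; if refinement splits a seed,
   every piece still reaching the seed level becomes its own candidate.
   Components are processed in decreasing-SUVmax order and voxels are
   claimed at most once, so candidates are always pairwise disjoint even
   when a refinement region would grow past its seed (possible when
   `fraction·SUVmax` falls below the seed level).
4. **SUVpeak admission.** In blood-pool mode a candidate is kept only if its
   SUVpeak — the maximum over ROI voxels of the mean SUV in a ~1 cm³ sphere,
   clipped at the grid boundary only — is *strictly* greater than the
   threshold.
5. **Volume filter.** Candidates with volume strictly below 2 cm³ are
   discarded (0.1 cm³ in the small-lesion preset); a candidate of exactly
   2.000 cm³ is kept.

Ties in candidate ordering (equal SUVmax) are broken by lexicographic
centroid so ids are stable. The exact internals of the original multi-foci
segmentation software are unpublished; this pipeline is a reconstruction
that honors every stated rule, and it is cross-checked bit-exactly against
an independent naive implementation (flood-fill components, per-voxel sphere
means) on hundreds of random small volumes.

Three presets are shipped: `percist42` (default), `suv2p5_41` (fixed 2.5 SUV
seed, 41% iso-contour) and `suv2p5_41_small` (the same with the 0.1 cm³
volume floor).

## Uptake classification

The production systems this package models use a trained convolutional
network to label each candidate as physiologic or suspicious. Such a network
is deliberately not part of this package; instead the classifier is a
pluggable contract with two implementations:

* **Oracle** — suspicious iff at least 50% (configurable) of the candidate's
  voxels lie inside the true lesion union; scores are 0/1. It exists to test
  the pipeline around the classifier under perfect classification.
* **Baseline** — logistic regression (C = 10, standardized inputs) on
  hand-crafted features: SUVmax, SUVpeak, volume, position inside the body
  bounding box, sphericity (`π^(1/3)(6V)^(2/3)/A`, surface area from a
  marching-cubes mesh, clipped into (0, 1]), and distances to the five
  canonical organ centers. Trained on oracle labels with a held-out split;
  the trained model serializes to a versioned JSON with its standardization
  constants.

The decision threshold on the suspicion score is 0.5 by default; raising it
can only shrink the suspicious set. Per-ROI scores from the baseline are not
calibrated against any external system's scores.

TMTV is the sum of the volumes of suspicious candidates — the candidates'
own 42%-iso-contour volumes, not reference volumes, so TMTV is an estimator
with the biases of the segmentation.

## Synthetic phantoms

The phantom emulates the statistics that drive the pipeline rather than
anatomy:

* an elliptic-cylinder body (background SUV 1.0) inside a 40×40×96 grid at
  4 mm spacing (160×160×384 mm field of view);
* five canonical organs (brain, heart, two kidneys, bladder) as
  Gaussian-blurred ellipsoids at fixed fractional positions, peak SUV 5.5–10;
* random physiologic foci (bowel uptake, muscle activation, inflammation):
  elongated ellipsoids (2–3× axis ratio), peak SUV 5.0–6.3, Poisson count
  with mean 12 — moderate-intensity, irregular uptake, in contrast to
  tumors;
* tumor lesions: spheres with peak SUV 6.5–12 and a Gaussian edge
  (default σ = 3 mm). The *true* lesion volume is the pre-blur binary mask
  volume, so iso-contour recovery is meaningful but imperfect, as on real
  images;
* a blood-pool cylinder whose sample mean/SD are calibrated to 1.6/0.5 SUV
  (the ~20-voxel region is too small for an i.i.d. draw to land reliably
  near the target SD, so the drawn sample is standardized before scaling);
* additive Gaussian noise in SUV space (σ = 0.15). We simulate
  post-reconstruction SUV images only; there is no Poisson count noise,
  scanner blur, or motion.

Cohort generation draws a per-subject lesion count (Poisson, mean 10) and a
log-normal true-TMTV target (median 240 cm³, log-SD 0.9), split across
lesions by a flat Dirichlet. Lesions are placed largest-first by rejection
sampling with keep-out margins around organs, other lesions and the aorta;
lesions that cannot be placed are skipped, which truncates the extreme upper
tail slightly. Realized cohorts have a right-skewed TMTV distribution with
median ≈ 200 cm³ and ~19–22 detectable candidate regions per subject
(target load ~24). All randomness flows from one root seed through spawned
child sequences, so cohorts are bit-reproducible.

Outcomes are simulated from a proportional-hazards model: exponential event
times with hazard `h₀·exp(β·x)`, `h₀ = 0.1/y`, `β = log(HR)` with HR 2.5 by
default, `x` the high-TMTV indicator (cutoff 240 cm³) or standardized
log-TMTV, administratively censored at 8 y (≈30% censoring under defaults).

**What passing tests show — and do not.** The oracle pipeline's perfect
confusion matrix and near-unit Dice demonstrate the *plumbing* is
self-consistent, not that detection would work on real images; phantom
contrast is generous and noise mild by construction. The baseline
classifier's ~90% held-out accuracy shows the feature interface carries
signal in a world where physiologic and tumor uptake differ in intensity and
shape; real-world accuracy would require the deep-learning classifier this
package deliberately leaves out.

## Evaluation layer

Candidates are matched against the per-subject *union* of reference lesions:
a candidate matches if at least 25/50/75% (inclusive) of its voxels lie in
the union, with 50% the primary rule. Suspicious ∧ matched = TP, physiologic
∧ matched = FN, physiologic ∧ unmatched = TN, suspicious ∧ unmatched = FP;
sensitivity, specificity and accuracy follow, displayed rounded to the
nearest percent with raw rates kept in machine output. Undefined rates (no
matched ROIs, say) are flagged rather than propagated as NaN.

Voxel agreement uses Dice, precision and recall between the suspicious union
and the reference union, with the conventions: both empty → 1, exactly one
empty → 0. TMTV agreement uses Spearman rank correlation (t approximation
for n > 10, exact permutation for n ≤ 10) and Bland–Altman analysis
reporting the median bias with empirical 2.5/97.5-percentile limits —
percentile limits are always used (TMTV differences are not normal in
practice), with the linear-interpolation quantile definition (numpy's
default) stated because percentile conventions differ.

## Prognostic layer

`PrognosticModel(records).fit()` performs the standard TMTV prognosis
workflow and returns a results object with `summary()` and KM/ROC plots.

* **Cutoff.** A 4-year-horizon ROC over observed TMTV values. The default
  estimator is the cumulative/dynamic time-dependent ROC with inverse
  Kaplan–Meier censoring weights (cases: observed events by the horizon,
  weighted by 1/Ĝ(T⁻); controls: subjects under observation past the
  horizon); a naive estimator that drops early-censored subjects is kept
  for transparency and coincides exactly with the weighted one when there
  is no censoring. AUC is the trapezoid over the upper staircase of the
  curve. The operating cutoff maximizes the Youden index with ties broken
  toward the smaller cutoff (favoring sensitivity).
* **Groups.** High TMTV = strictly above the cutoff. Kaplan–Meier curves per
  group (lifelines), with the 4-year rate read from the right-continuous
  step function; two-group log-rank test; univariate Cox regression for the
  high-vs-low hazard ratio with a 95% Wald interval. Tie handling is Efron
  (lifelines); an in-package Newton fit of the Breslow partial likelihood
  (tolerance 1e-9 on β, 50 iterations max) is available and agrees with
  Efron on tie-free data. Monotone likelihoods (complete separation) raise
  a convergence error rather than returning a divergent estimate.

Degenerate inputs fail loudly: no events before the horizon, no subjects at
risk at the horizon, constant TMTV, or a cutoff that does not split the
cohort all raise typed errors.

## Problem sizes used in the shipped experiments

The test-suite and acceptance experiments use: 24³–64³ grids for exact
cross-checks; a 50-subject default cohort for the end-to-end
self-consistency run; 30 subjects for the reported cohort quantities;
n = 2000 with 20 seeds for Cox hazard-ratio recovery. These sizes give
stable statistics (e.g. the HR estimate's standard error at n = 2000 is
~0.14 on the HR scale) while keeping a full run in minutes on one CPU.

## Known limitations

* No DICOM ingestion, resampling, or PET/CT co-registration: volumes and
  masks must share one grid.
* The phantom is statistical, not anatomical; absolute detection metrics on
  it do not transfer to patients.
* The classifier contract ships no trained deep model; the baseline is a
  reference implementation of the interface, not a clinical classifier.
* The time-dependent ROC variant is one of several in the literature;
  cutoffs from small cohorts are data-bound and should not be compared
  across estimators without care.
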
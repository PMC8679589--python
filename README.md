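# tmtvkit

Automated **total metabolic tumor volume (TMTV)** estimation for whole-body
¹⁸F-FDG PET, with the evaluation and prognostic machinery to validate it.

Baseline TMTV — the summed volume of all metabolically active tumor sites on
an FDG-PET scan — is a strong prognostic factor in diffuse large B-cell
lymphoma and other lymphomas, but measuring it normally requires an expert
to review every high-uptake region and discard physiologic uptake (brain,
heart, bladder, bowel, muscle). `tmtvkit` implements the fully automated
alternative: detect every high-uptake region, classify each as physiologic
or suspicious, and sum the suspicious volumes. It is aimed at quantitative
imaging researchers who want a reproducible, testable reference pipeline
and a synthetic ground-truth cohort to exercise it on.

## The pipeline

For each subject with SUV volume `V`:

1. **Blood-pool reference** — mean and SD of SUV in a 10×20 mm cylinder in
   the proximal descending aorta; PERCIST-style admission threshold
   `T = 2·SUV_mean + 2·SUV_SD`.
2. **Multi-foci segmentation** — connected components of `{SUV ≥ T}`,
   refined by a 42%-of-SUVmax iso-contour per region, admitted when
   `SUV_peak > T` (mean SUV in a 1 cm³ sphere), and filtered at 2 cm³.
   Alternative presets seed at a fixed SUV of 2.5 with a 41% iso-contour,
   with or without the 0.1 cm³ small-lesion floor.
3. **Uptake classification** — a pluggable classifier labels each candidate
   ROI *physiologic* or *suspicious* (in production systems a trained deep
   network; here a ground-truth oracle and a trainable feature-based
   baseline).
4. **TMTV** — `TMTV = Σ volume(ROI_i)` over suspicious ROIs, in cm³.

The evaluation layer matches candidates against reference lesions (≥25/50/75%
volume-overlap rules → TP/FP/TN/FN, sensitivity/specificity/accuracy), and
measures voxel agreement (Dice `2|A∩B|/(|A|+|B|)`, precision, recall),
Spearman rank correlation and Bland–Altman limits between TMTV estimates.
The survival layer finds an operating TMTV cutoff from a censoring-aware
4-year ROC by maximizing the Youden index (sensitivity + specificity − 1),
then compares low/high-TMTV groups with Kaplan–Meier curves, a log-rank
test, and a univariate Cox hazard ratio.

Because no public whole-body PET cohort with reference lymphoma
segmentations exists, the package ships a phantom generator producing
whole-body SUV volumes with canonical organs, physiologic foci, lesions of
known volume, realistic blood-pool statistics (mean ≈ 1.6, SD ≈ 0.5 SUV),
and proportional-hazards outcomes linked to TMTV. See `docs/methods.md`.

## Worked example

```python
import numpy as np
import tmtvkit as tk
from tmtvkit.survival import records_to_frame

# 20-subject synthetic cohort, oracle-classified, default PERCIST preset
cohort = tk.generate_cohort(tk.CohortSpec(n_subjects=20, seed=7))
clf = tk.OracleClassifier()
results = [
    tk.process_subject(f"S{i:03d}", vol, tk.PRESETS["percist42"], clf,
                       truth=truth, settings_name="percist42")
    for i, (vol, truth) in enumerate(cohort)
]
print(tk.tmtv_table(results).head(5).to_string(index=False))

ev = tk.evaluate_cohort(results)
rep = ev["confusion"]["rule_0.5"]
print("confusion:", rep.tp, rep.fp, rep.tn, rep.fn)
print("median Dice:", round(np.median(ev["agreement"].dice), 3))

# prognostic layer on a simulated proportional-hazards cohort (true HR 2.5)
model = tk.SurvivalModelSpec(hazard_ratio=2.5)
tmtv = np.random.default_rng(7).lognormal(np.log(240.0), 0.9, 2000)
recs = tk.simulate_survival(tmtv, model, seed=7)
fit = tk.PrognosticModel(records_to_frame(recs), endpoint="PFS").fit()
print(fit.summary().round(3).to_string(index=False))
```

Output:

```
subject_id   setting  tmtv_cm3  n_rois  n_suspicious  true_tmtv_cm3
      S000 percist42   185.664      20             9        162.304
      S001 percist42   195.072      16             1        168.448
      S002 percist42   174.272      20             9        152.064
      S003 percist42   198.272      28            13        214.208
      S004 percist42   342.464      24            13        330.496
confusion: 170 0 240 0
median Dice: 0.931
endpoint   auc  cutoff_cm3  hazard_ratio  hr_ci_low  hr_ci_high  high_tmtv_4y_survival  low_tmtv_4y_survival  logrank_p
     PFS 0.671     239.964         2.756      2.472       3.072                  0.349                 0.697        0.0
```

Reading this: each subject's estimated TMTV tracks its true lesion volume
(the 42% iso-contour volumes differ slightly from the pre-blur truth); with
the oracle classifier and the matching overlap rule there are no false
positives or negatives — the pipeline is self-consistent; the prognostic fit
recovers a cutoff at the generative threshold (240 cm³) and a hazard ratio
whose confidence interval covers the generative value 2.5.

The same experiment is available from a shell:

```bash
tmtvkit phantom --out data --n 20 --seed 7
tmtvkit run --data data --out run --preset percist42
tmtvkit evaluate --data data --run run --out eval.json
tmtvkit survival --tmtv run/tmtv.csv --survival data/cohort.csv --out surv.json
```

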
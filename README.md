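# periopred

Site-level prediction of non-surgical (step II) periodontal therapy
outcomes from routine clinical chart data.

Periodontitis therapy response is highly variable across patients, teeth
and probing sites. `periopred` provides the full analysis pipeline a
periodontal outcome study needs:

* a validated **long-format chart model** (one row per patient × tooth ×
  site, six sites per tooth in FDI notation) with a documented CSV format;
* the **2018-classification staging/grading engine** working from probing
  data alone: clinical attachment loss estimated as
  `CAL = PPD − 3 mm` (no recession) or `CAL = PPD + recession`,
  occluding-pair counting (max 14, third molars excluded),
  `bone loss [%] = CAL / root length × 100`, stage 1–4 from the maximum
  interdental CAL with severity modifiers, grade A–C from the
  bone-loss/age ratio and smoking, extent localized/generalized at the
  strict 30% threshold;
* **clinical missing-data imputation** (per-field non-occurrence /
  positive-default rules, median stress, mean BMI, donor-vote plaque,
  probing-depth-derived furcation grades), with per-cell provenance;
* three **outcome tasks** — post-therapy pocket-depth category (≤3 / 4–5 /
  ≥6 mm), pocket improvement, and pocket closure (PPD ≤3 mm, or 4 mm
  without bleeding on probing), the binary tasks restricted to
  baseline-affected sites (PPD ≥ 4 mm) with the adverse outcome as the
  positive class;
* a **patient-grouped benchmark**: 80/20 split and 10-fold CV grouped at
  patient level (no site of a patient crosses a split), class rebalancing
  (up/down-sampling, SMOTE) and categorical encoding (one-hot or target)
  fitted inside training folds only, a model zoo (prior dummy, logistic
  regression, random forest, XGBoost, MLP) tuned by seeded random search
  or a Gaussian-process Bayesian alternative on F1/Brier criteria;
* the **metric suite**: accuracy, precision, recall, F1, NPV, per-class and
  macro F1, binary and multiclass Brier (sum and halved conventions),
  Brier skill score, tie-corrected ROC AUC, calibration tables, confusion
  matrices, and Monte-Carlo Shapley feature attribution;
* a **synthetic cohort generator** reproducing the field's reported
  structure — baseline category proportions ≈ 79.8% / 14.6% / 5.6% and
  therapy transitions (≈95% of healthy sites stay healthy, ≈60% of 4–5 mm
  pockets close, ≈66% of ≥6 mm pockets improve) with covariate-dependent
  response — so the entire pipeline is exercisable without clinical data.

## Worked example

```python
import numpy as np
from periopred import (CohortConfig, generate_cohort, impute_dataset,
                       build_task_dataset, grouped_split, BenchmarkConfig,
                       tune_and_train, dummy_baseline, binary_metrics,
                       brier_skill, classify_patient)

cohort = generate_cohort(CohortConfig(n_patients=100, seed=1))
print(classify_patient(cohort, "P00000"))

task = build_task_dataset(cohort, "closure")          # adverse = non-closure
plan = grouped_split(task, test_fraction=0.2, seed=1) # patient-grouped
clf = tune_and_train(task, BenchmarkConfig(learner="logistic",
                                           tuning_criterion="f1",
                                           search_budget=5, seed=1),
                     train_patients=plan.train_patients)
test = np.isin(task.groups, list(plan.test_patients))
j = int(np.flatnonzero(clf.classes_ == 1)[0])
m = binary_metrics(task.labels[test], clf.predict(task.features[test]),
                   clf.predict_proba(task.features[test])[:, j])
ref = dummy_baseline(task.labels[~test])
mref = binary_metrics(task.labels[test], ref.predict(task.features[test]),
                      ref.predict_proba(task.features[test])[:, j])
print({k: round(v, 3) for k, v in m.items()},
      "skill:", round(brier_skill(m["brier"], mref["brier"]), 3))
```

prints (seed 1):

```
PatientClassification(patient_id='P00000', stage=3, grade='C',
    extent='generalized', max_interdental_cal=8, n_opposing=12,
    max_bone_loss_pct=57.14..., extent_pct=34.48..., n_teeth_present=29,
    n_teeth_max_stage=10)
{'accuracy': 0.693, 'precision': 0.459, 'recall': 0.157, 'f1': 0.234,
 'npv': 0.719, 'brier': 0.204, 'roc_auc': 0.614} skill: 0.029
```

The patient's deepest interdental attachment loss (8 mm) with 12 occluding
pairs yields stage 3; a bone-loss/age ratio above 1 yields grade C; 34.5%
of teeth at the stage-defining severity (> 30%) makes the disease
generalized. The tuned logistic model discriminates non-closing pockets
above chance (AUC 0.61 on this small test split) and edges out the
prior-probability dummy's Brier score (skill 0.03).

A CLI mirrors the stages:

```bash
periopred simulate --n-patients 100 --seed 1 --out chart.csv
periopred impute   --in chart.csv --out imputed.csv --report report.json
periopred stage    --in imputed.csv --out staging.csv
periopred label    --in imputed.csv --task closure --out bundle/
periopred evaluate --in imputed.csv --task closure --out eval.json
```

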
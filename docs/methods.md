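# Methods

## Chart data model

A periodontal chart is a long table: one row per patient × tooth × probing
site, six sites per tooth (mesiobuccal, buccal, distobuccal, mesiooral,
oral, distooral). Mesial/distal positions are the interproximal sites used
for staging CAL maxima and root-length lookup. Probing pocket depth (PPD)
and recession are whole millimetres — clinical probes read in 1 mm steps —
so non-integer values are rejected at validation, never rounded. Missing
values are explicit nulls end-to-end; the imputation module is the only
place a null is ever filled, and the CSV dialect (empty cell = missing,
`true`/`false` booleans) round-trips nulls exactly.

Validation rejects rows rather than repairing them (duplicate keys,
invalid FDI numbers, negative or non-integer measurements, out-of-range
ordinals) and reports every rejection with a reason; per-field missingness
counts are part of the report. Tooth anatomy (type, root count, furcation
capability) derives from FDI notation via a configurable table whose
defaults are: upper molars 3 roots, upper first premolars 2, lower molars
2, all other teeth 1.

## Staging, grading, extent

Clinical attachment loss is estimated per site as

    CAL = PPD − 3 mm        if recession = 0
    CAL = PPD + recession   if recession > 0

with 3 mm the average physiological sulcus depth. CAL is floored at 0:
shallow sites (PPD < 3, no recession) would otherwise produce negative
attachment loss, which has no clinical meaning.

Masticatory function is the count of standard occluding
maxillary–mandibular pairs (same intra-quadrant position, quadrant 1↔4 and
2↔3, positions 1–7; third molars excluded; maximum 14).

Bone loss is estimated without radiographs as `CAL / root length × 100`,
uncapped. Root lengths come from a table keyed by sex, arch and tooth type;
the shipped defaults are literature-typical means (e.g. upper canine
16.5 mm, lower molar 14.0 mm, females −0.5 mm) and are deliberately an
explicit, overridable input (`RootLengthTable.from_json`) so substituting a
study-specific table is auditable.

Stage is assigned from the maximum interproximal CAL:

* CAL 1–2 mm → stage 1; CAL 3–4 mm → stage 2,
* escalated to stage 3 when PPD ≥ 6 mm occurs at ≥ 2 non-adjacent teeth
  (non-adjacent = not immediate neighbours within a dental arch, including
  across the midline) or furcation involvement grade 2–3 is present,
* CAL ≥ 5 mm → stage 3 with ≥ 10 occluding pairs, stage 4 below that.

With integer millimetre inputs CAL is integer, so the gap between the
1–2 and 3–4 bands is unreachable (asserted in tests). CAL < 1 mm returns
an explicit "no periodontitis" sentinel rather than a fabricated stage 0.
Furcation evidence is taken as the patient maximum.

Grade uses the ratio of maximum percentage bone loss to age: < 0.25 → A,
0.25–1 (inclusive at both ends) → B, > 1 → C. Smoking acts as a grade
modifier: ≥ 1 cigarette/day lifts A to B, > 10/day lifts to C. The
literal band predicate in circulation makes grade B reachable by every
non-smoker through its OR clause (conditions overlap); the modifier
reading with precedence C > B > A is the default, and the literal
predicate remains available behind `strict=True` for comparison.

Extent is the percentage of teeth at the maximum stage out of teeth
present; strictly above 30% is generalized. A tooth counts as "at the
maximum stage" when its own maximum interproximal CAL reaches the lower
bound of the CAL band that determined the patient's stage (3 mm for stages
2–3 via the moderate band, 5 mm for stage 3/4 via the severe band).

The patient classifier composes these in order CAL → occlusion → bone loss
→ stage → grade → extent and returns every intermediate for audit. It
treats missing recession as 0 mm and missing furcation as no involvement —
the same non-occurrence reading the imputation module applies — so it runs
on raw or imputed charts alike.

## Imputation

Each field has its own clinically motivated rule. Signs recorded only when
present are imputed as non-occurrence: bleeding on probing, percussion
sensitivity, restorations, recession (0 mm), mobility (0), diabetes,
antibiotic use, family/orthodontic history, smoking ("none", 0/day).
Vitality and cold sensitivity default to the positive/normal response.
Stress uses the patient-level median (interpolated convention: mean of the
central order statistics at even counts), BMI the patient-level mean; both
are computed over one value per patient, not per site, to avoid weighting
by tooth count, and raise an instructive error when entirely missing.

Plaque: isolated missing cells become "no plaque"; patients with plaque
entirely missing get a per-site majority vote over donor sites from other
patients matching tooth type, the same site position and PPD within
± 1 mm (the "comparable PPD" window, configurable); ties and empty donor
pools fall back to "no plaque".

Furcation: single-rooted teeth always grade 0. Patients missing furcation
at some sites get grade 0 there; patients missing all furcation data get a
grade from total probing depth (PPD + recession): < 3 mm → 0, 3–6 mm
inclusive → 1, > 6 mm → 2. Both bounds are read inclusive so integer
totals partition with no gap or overlap (property-tested over 0–20).

Imputation is idempotent, never alters observed values, and tags every
imputed cell with its rule in the report. Identity fields, `ppd_t0`,
`ppd_t1`, age and sex have no rule: they are expected complete (recovered
from records upstream), and the feature builder raises if they are not.

## Outcome tasks

* `ppd_category` (multiclass): post-therapy PPD category — ≤ 3 mm (1),
  4–5 mm (2), ≥ 6 mm (3) — over all sites with a reevaluation measurement.
* `improvement` (binary): non-improvement of baseline-affected pockets.
  Improvement is a strict integer decrease in PPD; the minimum decrease is
  configurable (default 1 mm) since no universal threshold exists.
* `closure` (binary): non-closure, where closure is PPD ≤ 3 mm or exactly
  4 mm without bleeding on probing at reevaluation.

Binary tasks include only baseline-affected sites, defined as PPD ≥ 4 mm:
3 mm sites are clinically healthy and are not instrumented targets. The
positive class is always the adverse outcome — the minority event a
clinician wants flagged — so F1/precision/recall of a majority-vote
baseline are exactly 0 while its accuracy equals the favourable-outcome
prevalence.

Predictors are the baseline (T0) schema on three levels: patient (age,
sex, BMI, antibiotics, family history, orthodontic history, diabetes,
stress, smoking type, cigarettes/day), tooth (FDI number, tooth type, root
count, mobility, restoration, vitality, percussion, cold sensitivity) and
site (site position, PPD, recession, BOP, plaque, furcation). Categorical
predictors (sex, smoking type, FDI, tooth type, site) are encoded in the
model pipeline — one-hot, or target encoding with internal
cross-fitting — never at task-assembly time, so held-out labels can never
leak into an encoding (verified by a label-poisoning test).

## Benchmarking

All resampling is grouped at patient level: the 80/20 train/test split and
the inner holdout or 10-fold CV partition patients, never sites. Class
rebalancing (upsampling and downsampling to equal counts; SMOTE with
5-neighbour interpolation, falling back to upsampling with a warning for
classes smaller than the neighbour count) and encoders are fitted inside
each inner training fold.

The model zoo: a prior-probability dummy (prevalence vector as
probabilities, majority hard label, ties to the lowest class index),
logistic regression (saga solver; log loss binary, multinomial loss
multiclass; standardized inputs), random forest, XGBoost (log loss /
multiclass log loss) and an MLP. Tuning criteria are F1 or Brier for
binary tasks and macro F1 or multiclass Brier for the 3-class task
(Brier criteria minimized via negation). Search is seeded random search
over documented per-learner ranges (regularization strength, tree depth
and count, learning rate, hidden-layer sizes); a sequential
Gaussian-process expected-improvement search over the unit-cube-encoded
space is available as `search="bayesian"`. Random search is the default:
it is deterministic under the seed and dependency-light. A single
top-level seed derives every sub-seed (splits, rebalancing, search,
model initialization). The benchmark grid enumerates learner × criterion ×
rebalance × encoding; the full grid with both binary criteria is 5 × 2 ×
4 × 2 = 80 configurations per task.

## Evaluation

Binary: accuracy, precision, recall, F1 and NPV on the adverse-positive
convention with zero-division → 0; Brier as the mean squared error of the
adverse-class probability; ROC AUC as the tie-corrected rank statistic,
undefined (None) for single-class labels. Multiclass: per-class
one-vs-rest F1 (absent class → 0 with a warning), unweighted macro F1,
accuracy, and the multiclass Brier under a configurable convention — the
standard sum over the three squared probability errors, or the halved
variant, both reported because both circulate; the convention is attached
to every result. Brier skill is `1 − Brier(model)/Brier(dummy)`, None for
a perfect reference. Useful identities of the prevalence dummy (accuracy
= majority share q, majority-class F1 = 2q/(1+q), macro F1 = 2q/(3(1+q)),
Brier = Σ pₖ(1−pₖ)) are asserted in tests against direct computation.

Calibration tables use 10 equal-width bins on [0, 1] (half-open except the
last; bin count configurable; quantile binning intentionally not used so
empty regions are visible). Confusion matrices are reported raw and
row-/column-normalized with None (not NaN) for empty totals.

Feature attribution is a seeded Monte-Carlo Shapley sampler over
`predict_proba`: for sampled evaluation rows, random feature orderings are
walked by swapping features one at a time from a background row into the
explained row, and the per-class marginal contributions are combined by
mean absolute value. It operates on the raw predictor columns through the
full pipeline, so one-hot blocks aggregate automatically to their source
predictor. The ranking — not the raw values, which depend on the
background sample — is the stable contract. The same sampling scheme
serves every model class; an exact tree-path variant was considered and
not implemented, as rankings from the sampler are already stable at the
default sample sizes (60 rows × 8 permutations).

## Synthetic cohort generator

The generator emulates the reported structure of step-II therapy cohorts.
Defaults: baseline PPD category proportions (0.798, 0.146, 0.056);
transition matrix rows (healthy → [0.95, 0.05, 0], moderate →
[0.60, 0.33, 0.07], deep → [0.33, 0.33, 0.34] — deep pockets improving
with similar mass to either better category); within-category integer PPD
(1–3, 4–5, 6–10 mm with decaying mass); per-tooth edentulism probability
0.08 so occluding-pair counts vary; age ~ N(52, 12²) clipped to 18–90;
50% female; 25% smokers (Poisson cigarette counts, mean 12); 10%
diabetics; 20% antibiotic adjunct; 30% family history; BMI ~ N(26, 4²);
stress 1–10 (shifted binomial). BOP probability rises with PPD on a
logistic curve at both time points; plaque correlates with PPD; furcation
and mobility derive from probing depth with noise.

Covariates act only on the therapy response: a per-covariate log-odds
shift (defaults: −0.06 per cigarette/day, −0.5 diabetes, +0.6 antibiotics,
−0.05 per stress point) moves the improvement mass of the transition row
on the logit scale, applied to mean-centred covariates so the marginal
transition rates stay at the matrix values. Baseline severity is
covariate-independent by design — a documented simplification that keeps
parameter-recovery tests interpretable. Baseline PPD remains predictive of
all three outcomes through the category-dependent transition rows, which
is why tuned models beat the dummy on synthetic data, mirroring baseline
PPD as the dominant predictor.

What the generator does **not** emulate: spatial correlation of pockets
within a jaw beyond the shared patient covariates, measurement error and
examiner drift, informative missingness (injected missingness is
independent per field), and covariate effects on baseline severity.
Passing tests therefore demonstrate pipeline correctness and recoverable
signal under known conditions — not clinical-grade performance on real
charts.

## Problem sizes and numerics

The test suite runs cohorts of 20–40 patients (≈ 3,500–7,000 sites) for
pipeline checks and 300–500 patients (≈ 55,000–90,000 sites) for
law-of-large-numbers recovery of configured proportions; the acceptance
script uses 400 patients and a tuned logistic model with a budget of 3
random-search trials, sizes at which every quantity is stable to well
within the tolerances asserted. Tolerances on recovered proportions are
3–4 binomial standard deviations at the realized counts. All randomness
flows from `numpy.random.default_rng` seeded at the interface; hypothesis
property tests are derandomized.

## Known limitations

* The grade modifier reading resolves an internally inconsistent printed
  predicate; both readings are implemented but only one can match any
  particular external dataset's conventions.
* Root lengths are population means; per-tooth radiographic lengths would
  change bone-loss percentages and hence grades near band boundaries.
* The stage-3 escalation from the moderate CAL band is implemented as
  printed; whether it should also apply at CAL ≥ 5 mm is left as printed
  (it does not), and furcation evidence is patient-max rather than
  requiring multiple involved teeth.
* The plaque donor pool spans all patients; a within-patient pool is a
  plausible alternative reading.
* SMOTE interpolates in the encoded feature space, so synthetic samples
  can fall between one-hot vertices; tree models are insensitive, linear
  models mildly regularized by it.
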
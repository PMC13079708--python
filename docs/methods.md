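# Methods

## Scope and data model

The unit of analysis is the visit: one patient contact with a recorded set
of active substances, plus date, sex, age and optional diagnosis.  Cohorts
are longitudinal (patients contribute 1–13 visits in the emulated setting),
so every split, fold and bootstrap operates on patients, never on visits.
Inclusion requires at least two documented medications and age ≥ 18 at the
visit; exclusions are logged with reasons.  Drug identity is a canonical
string (case-folded, trimmed, whitespace-collapsed); matching against the
knowledge bases is exact on canonical names, with no fuzzy or synonym
resolution — synonym handling, if needed, belongs in a preprocessing step
that rewrites the cohort file.  Drugs absent from a reference list score 0
in every component (closed-world rule), and the knowledge-base files are
versioned snapshots: interaction knowledge changes over time, so
reproducibility requires pinning the tables used.

## Component scores

Five per-visit components feed the composite; two further quantities
(the summed QT score and the serotonergic count) are computed for
description only.  All components are evaluated over the *unique* drug set:

| component | definition | range |
|---|---|---|
| DDI score | 3·N_major + 2·N_moderate + 1·N_minor over all C(n,2) pairs | 0 … 3·C(n,2) |
| polypharmacy | 1 if ≥ 5 unique drugs | {0,1} |
| QT max | max per-drug score; known=3, possible=2, conditional=1 | {0..3} |
| ACB score | sum of per-drug burden scores 1–3 | 0 … 3n |
| serotonergic any | 1 if ≥ 1 listed agent | {0,1} |

Pair classification is symmetric and self-pairs are rejected.  Conflicting
duplicate rows in a reference table (same pair or drug, different value)
are a hard load error rather than last-wins, since a silently corrupted
table would bias every downstream score.

One documented wrinkle: descriptive prose sometimes glosses a QT-max of 2
as "conditional"; the per-drug mapping implemented here is the canonical
one (possible = 2, conditional = 1) throughout.

## Composite, rescale, label

Standardization parameters (μ, σ per component; sample SD, ddof = 1) are
fitted on an explicit reference set and stored with the fit.  The composite
is the unweighted mean of the five z-scores — equal weights are the
baseline because no validated differential weighting exists for these
domains.  Conventions for edge cases:

* a component constant on the reference set is flagged degenerate and
  contributes z = 0 (with a warning) rather than poisoning the composite —
  this matters on small or deliberately constrained synthetic cohorts;
* the 0–10 display scale maps the reference minimum to 0 and maximum to 10;
  out-of-reference values extrapolate linearly and are clipped to [0, 10]
  for display while the unclipped value is retained (`pars_rescaled_raw`);
* the High-risk threshold τ₇₅ is the linear-interpolation 75th percentile of
  reference composite values, and the label rule is inclusive (≥ τ₇₅), so
  prevalence is ~25% up to ties;
* risk bands on the display scale are half-open [0,3), [3,6), [6,10]: the
  nominal band edges overlap at their endpoints, so a deterministic
  convention is required.

The reference set is an explicit argument everywhere.  Descriptive runs use
the full cohort (so the mean composite is exactly 0 and the rescaled range
is exactly [0, 10] by construction); modelling runs pass the training
visit ids, so that held-out data never influence μ, σ, min, max or τ₇₅.
The leakage discipline is testable: deleting the held-out rows and
refitting reproduces identical parameters.

## Screening model

An L2-penalized logistic regression predicts the High-risk label from a
sparse binary drug-indicator matrix (vocabulary fixed on the training data;
out-of-vocabulary drugs at test time are dropped) plus age (continuous,
standardized with train-fitted parameters) and sex (F = 1, M = 0).  The
engineered components and the composite itself are excluded from the
predictors by construction, and the design matrix asserts this.  A
drugs-only variant (no demographics) is used to rank drugs by association.

Defaults, all surfaced in the API and stored in model metadata: C = 1.0, no
class weighting, lbfgs solver, tolerance 1e−6, iteration cap 5000.  The
exact penalty strength is a convention, not an estimate; coefficients and
odds ratios should be read as regularized associations.

Validation schemes:

* 80–20 patient-level split stratified by a per-patient indicator of having
  ≥ 1 High-risk visit;
* the same split with combined stratification by age group (< 65 / ≥ 65 at
  first visit) × sex × High-risk indicator — 8 strata; strata with fewer
  than two patients are merged into the stratum differing only in age group
  (logged);
* 5-fold GroupKFold with patient id as the group; calibration for
  cross-validated models uses pooled out-of-fold predictions.

The screening alert applies an inclusive fixed cutoff of 0.30 to the
predicted probability; this is an operating threshold on the model output
and is conceptually distinct from the τ₇₅ label rule.  For threshold
sensitivity, metrics are reported on a fixed grid {0.30, 0.40, 0.50, 0.60}
together with F1-optimal and Youden-optimal (J = recall + specificity − 1)
cutoffs searched over the sorted unique *training* probabilities and then
evaluated on test; with constant predictions the optimum is undefined and
falls back to the grid minimum.

Uncertainty uses a patient-level percentile bootstrap (default 2,000
replicates): patients are resampled with replacement, duplicated patients
keep distinct identities, the statistic (AUC, or per-drug odds ratio via
refit) is recomputed per replicate, and replicates where it is undefined
(single-class resamples) are dropped and counted.  AUC uses the midrank
(trapezoidal) tie convention.  Calibration reports the Brier score and a
10-bin quantile reliability table whose counts conserve n; fully tied
predictions collapse to a single bin.

The odds-ratio table reports only drugs present in ≥ 20 cohort visits
(rare exposures give unstable penalized estimates), sorted by coefficient.

## Companion analytics

Variance inflation factors use OLS of each component on the other four with
intercept, VIF = 1/(1 − R²); perfectly collinear components are flagged
infinite.  Quartile discordance counts visits with < 5 drugs yet DDI score
≥ Q75 and polypharmacy visits with DDI score ≤ Q25; quartiles are computed
over all visits and comparisons are inclusive, exactly as defined.  Patient
profiles aggregate per-patient peak/mean display scores and High-risk visit
counts, ranked by a chosen key with deterministic tie-breaks (secondary key
mean display score, then stable patient order); outputs are de-identified
to rank, sex and age decade.  Top-visit reports rank by display score with
optional one-representative-per-regimen deduplication.

## Synthetic cohorts

The generator emulates the structure of a mid-size ambulatory psychiatry
service: 680 patients by default, 68.5% female, ages from a normal(60.1,
18.3) truncated at 18, visits per patient from a geometric distribution
with p = 1 − √½ truncated at 13 (sample median ≈ 2.5), and regimens of
2–10 drugs whose size and CNS share rise with a latent per-patient severity
propensity (Beta(2,2) plus a mild age tilt), giving ~50% polypharmacy.
Regimens persist across visits with probability 0.8, with small random
add/drop edits otherwise.  The synthetic vocabulary has seven classes —
four CNS (antipsychotic, antidepressant, sedative, anticholinergic adjunct)
and three somatic (cardiovascular, metabolic, respiratory) — and the
knowledge-base generator concentrates QT/ACB/serotonergic annotations and
dense interaction pairs on the CNS classes, so DDI burden co-varies with
drug count as in real prescribing.  Everything is deterministic given
(config, seed).

What the generator does **not** emulate: real pharmacology of named drugs,
dose/duration, diagnosis structure, seasonal visit patterns, or the exact
marginal distributions of the components in any particular clinic.  Passing
tests on synthetic cohorts therefore demonstrate the correctness and
leakage-hygiene of the machinery, not clinical performance on any real
population.

### Planted truth and the recovery experiment

Each generated cohort carries a per-drug planted effect used to validate
the whole pipeline by parameter recovery.  Labels in the recovery
experiment come from the pipeline's own percentile rule on a train-only
reference — the planted propensity only shapes *who is prescribed what* —
so the experiment exercises the label construction exactly as used on real
data.

Because the label is a monotone function of the drug set, a drug's
recoverable coefficient sign combines two mechanisms: cluster membership
(risky drugs flow to high-propensity patients) and within-regimen
substitution (a drug displaces alternatives, so its *relative* risk load
matters).  The planted sign is therefore: positive for CNS drugs with
above-average risk load (annotations plus severity-weighted interaction
degree — both mechanisms agree); ambiguous (excluded) for below-average CNS
drugs, where the mechanisms oppose; negative for somatic drugs with no risk
signal at all (pure substitution); ambiguous for annotated somatic drugs.

The strong-signal preset makes recovery well-posed: a sharply bimodal
patient mix (Beta(0.6, 0.6), CNS share 0.08–0.92), a *constant* regimen
size of 7 so that composition rather than count carries the signal and
somatic presence strictly displaces CNS drugs, persistence 0.95, and fully
clean somatic drugs.  A constant regimen size makes the polypharmacy
component degenerate on these cohorts, which the composite handles by
design (z = 0).  The null preset zeroes all planted effects and replaces
the percentile label with i.i.d. Bernoulli(0.25) noise — with no planted
effects a percentile label would still be a deterministic function of the
drug set, so chance-level discrimination is only expected against
feature-independent labels; the null arm reports pooled out-of-fold AUC
from patient-grouped 5-fold cross-validation for stability.  If a generated
label vector is single-class on either side of a split, the cohort is
regenerated with the next seed and the regeneration is logged in the
report.

## Problem sizes used in tests and reports

The test suite and the reference-results script run on deliberately modest
cohorts chosen as the smallest sizes at which each property is sharp:
150-patient cohorts (~500 visits) for unit and oracle tests, a 2,000-visit
sample for the percentile-prevalence check (the prevalence bound 1/n is
exact once the score distribution is tie-free at the quantile boundary —
the sampler advances deterministic sub-seeds until that precondition
holds), 600-patient cohorts for recovery experiments, 100 repeated splits
for the grouped-validation integrity check, and reduced bootstrap replicate
counts (~200) in tests against the 2,000-replicate production default.

## Known limitations

* Exact-string drug matching; combination products and salts must be
  resolved upstream.
* No dose, route or duration awareness; interaction logic is pair-table
  lookup, not mechanistic (no CYP inference).
* Equal component weights are a baseline, not a learned weighting.
* The screening model is linear in drug indicators; interactions between
  drugs affect the label but are not modeled as features.
* Bootstrap CIs are percentile intervals; no BCa correction.
* Coefficients from penalized fits on observational co-prescription data
  are associations, not causal effects, and negative coefficients must not
  be read as protective.
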
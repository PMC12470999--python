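# Methods

## Problem and model

A wrong-blood-in-tube (WBIT) error assigns a blood sample to the wrong
patient record.  Detection is framed as binary classification of *pairs*
of consecutively drawn complete-blood-count (CBC) samples: a pair is
non-WBIT when both draws come from the same patient and WBIT when the
second (more recent) draw actually belongs to someone else.  The feature
vector of a pair is the element-wise first-order difference of its nine
analyte values, second minus first, in native units (ERY ×10⁶/µL, HB
g/dL, HK %, MCV fL, MCH pg, MCHC g/dL, RDW %, PLT ×10³/µL, LEUKO
×10³/µL).  Under a same-patient pair, each Δ is within-individual
variation around a personal set point; a swap replaces the second draw's
set point, injecting between-individual variation.  The classifier is a
Random Forest with class-balanced sample weights and otherwise library
defaults; the forest size is pinned in `PipelineConfig.n_trees`
(default 100) so results reproduce across library versions.

## Pipeline conditions (defaults)

| parameter | default | meaning |
|---|---|---|
| transfusion_window_days | 90 | drop samples drawn ≤ 90 d after a transfusion (donor blood shifts the recipient's CBC away from their set points); both endpoints inclusive |
| max_pair_gap_days | 30 | consecutive draws further apart are not paired (biological drift dominates) |
| wbit_interval_hours | 24 | swap partners must share the calendar bin of their second sample |
| wbit_target_fraction | 0.5 | converted-pair target per (day × ward) group |
| train_days / test_days | 1269 / 316 | temporal split proportions of the motivating 1585-day cohort; examples and tests use scaled-down spans with the same ~80/20 ratio |
| cv_folds | 5 | stratified, shuffled, one partition shared across all subsets |
| bootstrap_iterations / ci_level | 1000 / 0.95 | percentile bootstrap by case resampling |
| assumed_prevalence | 0.005 | deployment WBIT rate for PPV adjustment (realistic estimates are ~4 per 1000) |
| decision_threshold | 0.5 | probability cut-off for confusion metrics |

## Swap simulation

Pairs are grouped by (24-h bin, ward) of the second sample, because a
mislabeled tube can only plausibly be confused with tubes drawn around
the same time and place.  Within a group holding ≥ 2 distinct
second-sample patients, `ceil(target · group_size / 2)` swaps are drawn;
each swap picks two not-yet-swapped pairs with different second-sample
patients (random order, greedy partner matching, deterministic given the
seed) and exchanges their second samples, labeling both WBIT.  Groups
with fewer than two distinct patients pass through untouched, and an odd
eligible group retains one unmatched non-WBIT pair.  Consequences worth
knowing:

* a group of two converts fully; tiny-group granularity means the global
  fraction only approaches the 50 % target on cohorts with reasonably
  large groups (dense test cohorts land within ±0.02);
* sparse cohorts (many wards, few same-day draws) convert well below the
  target — that is faithful behavior, not a bug;
* each pair participates in at most one swap, so a swap can never be
  silently undone by a later one;
* swaps permute second samples within a group, so the per-group multiset
  of second vectors is exactly preserved (asserted in tests), and group
  keys and gap metadata always describe the pair as originally drawn.

Since every input pair is same-patient, requiring the two *second*
patients to differ guarantees the swapped pairs' first and second
patients differ, so WBIT labels and patient mismatch coincide exactly.

## Synthetic cohort generator

Each patient receives a set point per measured analyte (ERY, HB, MCV,
RDW, PLT, LEUKO) from a between-individual distribution; draws scatter
around the set point with a within-individual CV.  Defaults place
population means and total SDs near a large central-European inpatient
cohort and take within-individual CVs from published biological-variation
estimates (MCV 1 %, RDW 2.5 %, ERY 3.5 %, HB 3 %, PLT 9 %, LEUKO 14 %).
PLT and LEUKO use a lognormal family (right-skewed populations), the
erythrocyte indices a normal family; for the normal family the total SD
is exactly `mean·√(cv_between² + cv_within²)`, and the lognormal family
matches the same total SD by partitioning the log-variance
proportionally.  HK, MCH, MCHC are derived exactly through the analyzer
identities, never sampled — preserving the redundancy structure of real
panels.  Draw counts per patient follow a {1, 2, 3–5, >5} stratum
mixture, inter-sample gaps a {<1 d, 1–7 d, 7–30 d, >30 d} mixture, wards
are constant within an admission episode (a gap > 7 days starts a new
episode), and a configurable fraction of patients receives a uniformly
timed transfusion event.

The planted-signal variant (`planted_signal_variation`) keeps realistic
between-individual spread only for chosen signal analytes (default MCV,
RDW; within-CV floored at 0.8 %) and collapses every other measured
analyte's between-individual CV to 0.4 % while inflating its within-CV,
so only the signal analytes' deltas separate the classes.  Derived
analytes inherit an attenuated echo of the MCV signal (HK = ERY·MCV/10),
which is exactly what makes the recovery test non-trivial.

**What the generator does not emulate.** Measured analytes are sampled
independently per patient, so the strong physiological ERY–HB–HK
correlations of real blood are absent and the derived analytes (MCH,
MCHC) have wider marginal distributions — and carry more independent
signal — than in real data.  There is no pathology, treatment drift,
analyzer noise or missingness structure, and no latent real WBIT
contamination.  Synthetic cohorts are therefore *easier* than hospital
data: full-panel F1 and AUC run several points higher than on a real
cohort, and the prevalence-adjusted PPV can saturate at 100 % when the
held-out false-positive rate hits zero at the target sensitivity.
Passing tests validate the pipeline's mechanics and ranking structure
(MCV/RDW dominance, subset ordering, metric calibration), not absolute
real-world performance.

## Model search and statistics

Cross-validation is stratified K-fold with shuffling; a single partition
(fixed by the seed and the labels) is shared across every subset so that
per-fold scores stay aligned, which the paired t-tests require.
Stratification itself is a design choice for class-balance stability on
small folds.  Subsets of equal size are ranked by mean F1 with
lexicographic tie-breaks for deterministic reports.  The paired t-test
uses two conventions for degenerate inputs: all-zero fold differences
give p = 1, zero variance with nonzero mean gives p = 0.

The bootstrap is percentile, case-resampling, chosen as the simplest
defensible reading of "bootstrap confidence intervals"; single-class
resamples are redrawn (cap 100 per iteration).  PPV operating points are
selected without ROC interpolation — the vertex with the smallest
tpr ≥ target, then smallest fpr — a conservative, reproducible choice;
with the assumed prevalence set to the sample prevalence the adjustment
reproduces the raw PPV exactly (asserted in tests).

## Importance metrics

MDI comes from the fitted forest (normalized, sums to one).  Permutation
importance is implemented in-package because its contract here —
per-repeat exclusion of undefined metrics and clipping of negative mean
drops — is not exposed by library implementations; it is cross-checked
against one on clean data.  Defaults: F1 drop on held-out data, 10
repeats.  Shapley attribution is a path-dependent tree Shapley
implementation (`wbitlab._treeshap`): per-leaf decomposition over the
distinct features of each root path, with absent features weighted by
training cover fractions, reduced to an elementary-symmetric-polynomial
recurrence and evaluated in a numba kernel.  It satisfies local accuracy
(attributions + base = predicted probability, asserted to 1e-6) and is
verified to 1e-10 against an independent brute-force subset-enumeration
oracle on ≤ 4-feature models.  Global importance is the mean absolute
attribution over all evaluated samples for the WBIT-probability output.

## Problem sizes in tests and the acceptance script

Simulations are sized for single-core desk runs as the package's own
test design: dense swap-balance cohorts use ~4200 patients over 40 days
and 2 wards (≥ 5000 pairs, all groups ≥ 4); the full 511-combination
search runs on a ~1100-pair cohort with 2 folds and 50 trees (the
combinatorial claims do not depend on cohort size); planted-signal
recovery uses ~2000 pairs with 5 folds and 50 trees; bootstrap coverage
uses 300–500 replications of n = 200 Gaussian samples.  All seeds are
explicit, and the acceptance script derives every seed from its `--seed`
argument.

## Known limitations

* Independent per-analyte set points (no inter-analyte correlation
  structure); see above.
* The ~50 % conversion target is interpreted per eligible group with
  `ceil` granularity; whether the original procedure rounded up or down
  in odd groups is ambiguous, and small-group cohorts make the
  difference visible.
* Singleton-patient status is re-checked only after the transfusion
  filter (the documented stage order); an optional re-check after
  panel filtering exists but is off by default.
* Missing-analyte imputation, alternative learners, quadruple/time-series
  inputs and outlier-based cleaning of latent WBIT are out of scope.
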
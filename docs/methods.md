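# Methods

## Scope and model

`mmis` scores rare missense variants in genes relevant to primary
mitochondrial disease. The scorer is a penalized logistic regression on an
annotated feature vector x:

    Pr(pathogenic | x) = sigmoid(b + sum_i w_i x_i)

fitted by a deterministic convex solver (lbfgs, tolerance 1e-6, at most
1000 iterations). L2 regularization is the default (C = 1.0); L1 is
available through the hyperparameter mapping. The training set is assumed
label-balanced, so no class weighting is applied. |w_i| is reported as
feature importance, with ties broken alphabetically so the ranking is
deterministic.

The annotation half is deliberately thin: it performs interval membership
against a gene registry (1-based inclusive coordinates, the VCF
convention), selects one representative transcript per gene, and joins
typed values from per-level tables. It does not call consequences itself —
a consequence term is taken from a variant-level source column when
present, else from a caller-supplied VCF INFO key. Multi-allelic records
are decomposed per ALT before filtering because scoring is per-allele, and
a variant inside two panel genes is emitted once per gene, since
transcript-level annotations differ between them. When the MANE transcript
is not among the observed transcripts the fallback is the
lexicographically smallest observed id, logged, so the choice is auditable.

## Feature pipeline

Order is fixed: imputation first, then normalization. Neighbour distances
on raw values are scale-sensitive, but normalizing first would let the
column minima/maxima depend on values that are about to be replaced; the
chosen order is documented and covered by tests rather than left implicit.

**KNN imputation** (default k = 5, configurable). The distance between two
partially observed rows is the Euclidean distance over mutually observed
features rescaled by sqrt(n_features / n_observed) — the standard
incomplete-data convention. A missing cell is the unweighted mean of that
feature over the k nearest donor rows that observe it; every donor tied at
the k-th distance is included, so results do not depend on row order. The
fitted state stores the completed training matrix; new rows are imputed
against it. A row sharing no observed feature with any donor falls back to
the plain feature mean. Requirements: at least k+1 rows and no fully
missing column.

**Normalization** is per-feature min-max to [0, 1] on training data.
Min-max was chosen because many inputs (predictor scores, allele
frequencies) are naturally bounded; transformed held-out values may leave
[0, 1], which downstream code accepts. Constant features get scale 1, map
to 0, and are flagged. `denormalized_coefficients` converts fitted weights
back to the raw feature scale: w_raw = w / (max - min), with the matching
intercept shift.

Both states are fitted on training rows only; inside cross-validation they
are part of the per-fold pipeline, so held-out rows can never influence
them. This is asserted by a sentinel test that corrupts held-out rows with
extreme values and checks the fold-fitted parameters bit-for-bit.

## Model selection

Nested stratified cross-validation: an inner 5-fold grid search
(accuracy-scored) tunes hyperparameters on each outer-training fold, the
refit pipeline is scored on the outer held-out fold, outer cv = 10 by
default. Six candidate families are compared — AdaBoost, decision tree,
random forest, logistic regression, k-neighbours, SVM — with compact
default grids (LR C over {0.1, 1, 10}; tree depth {3, 5, none}; forest 100
trees; k in {5, 11}; SVM rbf/linear at C = 1; AdaBoost 50/100 estimators).
The summary metrics (accuracy, precision, AUC, F1, recall, MCC) are
computed on pooled out-of-fold predictions — each row is predicted exactly
once by the fold that held it out — while per-fold accuracies are reported
separately as mean ± sd. Folds are stratified with a fixed, logged seed;
with a balanced training set stratification is near-neutral but protects
against degenerate folds.

The parameter-recovery harness fits with C = 1e6 (effectively unpenalized):
penalized maximum likelihood is biased toward zero, so an unpenalized fit
is the right estimator when the question is whether the true generative
coefficients are recovered. The package default for production fits stays
at C = 1.0.

## Evaluation conventions

* Classification is strict: predicted pathogenic iff score > t. The same
  strictness backs the stratification bounds (pathogenic Pr > 0.75, benign
  Pr < 0.15, VUS in between), so one convention serves both.
* Rows without a score are excluded from every metric and counted in the
  `missing` field; undefined ratios are reported as an explicit marker
  (None / "." in TSV), never silently 0.
* The ROC sweep groups tied scores into one step, starts at (0,0) and ends
  at (1,1); its trapezoidal area equals the tie-corrected normalized
  Mann-Whitney U, which the tests verify pairwise. Average precision is
  the step-wise sum over the descending-score sweep.
* The "optimal" threshold maximizes Youden's J = TPR − FPR over the
  curve's thresholds, smallest threshold on ties. Youden's J is an
  assumption — it is the standard ROC-derived choice, but other criteria
  exist and the threshold is always computed from data, never hard-coded.
* Percentages are rounded to 2 decimals and unit-scale statistics to 3
  only at the reporting boundary; full precision is retained internally.

## Exome benchmark

Background exomes are frequency-filtered candidate lists (common variants
with MAF > 1% removed; a missing MAF is treated as rare and kept). Exactly
one causative variant is spiked per exome; its rank in the
descending-score list uses pessimistic tie handling (placed after every
non-causative tie), so reported ranks are conservative. Candidate-list
size is the percent of scored variants above the tool's recommended
threshold, with unscored variants removed from the denominator and
flagged. Cohort-size defaults of 29 and 170 exomes at ~400 variants each
echo the two standard benchmark cohorts. Rank comparisons between tools
use the Mann-Whitney test: for n_a·n_b ≤ 200 the exact tie-aware
permutation null is computed by a subset-sum dynamic program over doubled
midranks, p = min(1, 2·min(P(W ≤ w), P(W ≥ w))); larger groups use the
tie-corrected normal approximation.

## Synthetic fixtures

The generators produce: registries with non-overlapping synthetic
intervals (13/321/1127 genes per category by default, 1–5 transcripts per
gene); typed annotation schemas and matching source tables with
missing-at-random tokens; VCFs with a controlled fraction of in-panel
positions; labeled matrices with standard-normal continuous features,
Bernoulli(0.5) booleans, uniform small integers, and labels from the
logistic model itself; background exomes with Beta(0.2, 20) MAFs and
Beta(2, 5) background scores versus Beta(8, 2) causative scores. Seeds are
mandatory arguments, never global state.

Because the label model matches the predictor's assumption exactly,
parameter recovery is a sharp end-to-end check. What the fixtures do *not*
emulate — and what passing tests therefore cannot show — includes real
inter-feature correlation, coverage-driven (non-random) missingness, real
allele-frequency spectra, and the label noise of curated clinical
databases. Published table values obtained on curated real-data sets
(algorithm-comparison metrics, real-tool ROC/PR curves and their
thresholds, real-cohort exome percentages and ranks) are consequently out
of reach at desk scale; the pipeline instead produces same-shaped reports
from the synthetic fixtures, and the property suites pin the arithmetic.

## Problem sizes and numerical choices

The shipped acceptance run uses n = 5000 for recovery, n = 400 with 5
outer / 3 inner folds for nested CV, n = 600 held-out rows for evaluation,
and 29 exomes of ~400 variants — sizes chosen so the whole run completes
in seconds while keeping binomial noise well inside the reported
tolerances. Degenerate inputs are handled explicitly: empty registries and
header-only tables load cleanly; a single-class label vector, an all-zero
confusion matrix, an empty rank list, or an unscored causative variant
raise typed errors rather than returning misleading numbers.

## Known limitations

JSON model persistence is defined for the logistic family only (its state
is a coefficient vector plus preprocessing parameters); the other five
families exist for model comparison and live only in memory. Consequence
calling, liftover, haplogroup analysis and the content of any real
annotation database are out of scope — the schema is user data. Scores are
not recalibrated (no Platt/isotonic step); the stratification cutoffs are
conventions, not fitted quantities.
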
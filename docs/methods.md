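# Methods

## Survival-class formulation

Overall survival in months (a non-negative integer) is binned into six
ordinal classes with inclusive upper bounds: 0–12 → 0, 13–24 → 1, 25–36 → 2,
37–48 → 3, 49–60 → 4, >60 → 5. The terminal class pools all survivors past
five years; there is no censoring model — the formulation treats the task as
plain 6-class classification, not time-to-event analysis, so
survival-analysis machinery (Cox models, concordance) is out of scope.

## Preprocessing pipeline

* **Imputation.** Missing categoricals are filled with the per-variable mode
  (ties broken lexicographically), missing survival months with the rounded
  median. The mode/median source defaults to the dataset itself; the
  experiment pipeline passes the training split as the reference so
  validation/test records are filled without leaking their own
  distributions. Mode imputation is the simplest deterministic choice for
  all-categorical predictors.
* **Split.** 70/10/20 train/validation/test with floor rounding
  (n = 581 → 406/58/117), stratified by survival class by default: each
  class is allocated by the same floor rule and leftovers go to the parts
  with the largest fractional entitlement, so global sizes are exact and
  per-class proportions are within one record. A fixed seed reproduces the
  partition exactly.
* **Oversampling.** Random duplication with replacement up to the
  majority-class count, applied **after** splitting and to the training
  split only — oversampling before splitting would leak duplicated records
  into the test set and inflate every metric. No synthetic interpolation
  (SMOTE-style) is used: with purely categorical one-hot predictors,
  interpolated records would not be valid patients.
* **Encoding.** One column per (variable, level) in schema order; each
  record contributes exactly 15 ones. The encoding is bijective on the
  categorical content.

## The fuzzy deep learning network

Inputs are the d ≈ 50 one-hot columns. Each feature carries M = 2 Gaussian
membership functions (low/high for a binary column); centers initialize at
per-feature quantiles of the training data (falling back to a [0, 1] grid
for degenerate columns). Initial spreads are half the adjacent-center gap,
floored at 0.1 **and at √d/4**: a rule's firing is a product of d
memberships, so the gaps between rules' summed log-memberships grow with d,
and without the dimension-dependent floor the normalized firing collapses at
initialization to a hard winner-take-all partition — all but one rule stop
receiving gradient and each rule's consequent overfits its own small cell.
√d/4 keeps the spread of summed log-memberships O(1); spreads remain
trainable and are clamped at 1e-3 during SGD.

R = 16 rules take their antecedents from prototype training records (the
nearest MF per feature of a seeded random sample); the antecedent structure
is fixed while everything else trains. Firing strengths are computed as
exponentials of summed log-memberships and normalized to sum to one — the
weighted-average defuzzification is invariant to this common rescaling, and
the normalized form is exactly a softmax, which keeps the backward pass
simple and stable. Each of K = 8 aggregation units carries affine
consequents f_rk(x) = P_rk·x + b_rk and outputs the standard weighted
average Σ_r w_r f_rk / Σ_r w_r. A dense rectifier stack (64, 32) and 6-way
softmax head complete the network. A full grid of rules over ~50 inputs is
combinatorially impossible (2^50 antecedent combinations); a fixed small
rule bank with data-driven antecedents is the standard scalable neuro-fuzzy
compromise.

Two defuzzification conventions are exposed in the fuzzy core: the
conventional weighted average Σ w_i f_i / Σ w_i (default, bounded by
[min f, max f], scaling-invariant) and a literal variant
Σ w̄_i f_i / Σ w_i that weighs the numerator by separate center-of-area
terms. The network uses the conventional form; the literal form is kept for
exact reproduction of the written aggregation rule, whose mixed numerator/
denominator weights do not yield a weighted mean.

**Training.** Mini-batch SGD (batch 32) on categorical cross-entropy;
gradients for every parameter group — MF centers and spreads, consequents,
dense weights — are derived analytically and verified against central
differences (max relative error ~1e-6 in the shipped check). Early stopping
monitors validation accuracy with patience 12 and restores the best-epoch
parameters. The clinical-scale learning rate default is 1e-5; desk-scale
runs use 3e-2 because at a few hundred records per class the 1e-5 rate does
not move the loss within any reasonable epoch budget. Loss choice
(cross-entropy), hidden sizes (64, 32), rectifier activation, and max 500
epochs are conventional defaults for small tabular data. Everything is
driven by explicit integer seeds; two runs with the same seed are
bit-identical.

## Baselines

The dense baseline is the identical stack minus the fuzzy front end (inputs
straight into the 64/32/6 head), trained by the same protocol and seeds.
The SVM uses an RBF kernel with C ∈ {0.1, 1, 10, 100} × γ ∈ {1e-3, 1e-2,
1e-1, 1} chosen by 5-fold stratified cross-validated mean accuracy, ties
to smaller C then smaller γ; its ROC scores are one-vs-rest decision
values since no probability calibration is specified. The random forest
uses exactly 10 trees with the entropy criterion, unlimited depth, √d
features per split and bootstrap resampling; scores are vote fractions.
SVM and forest fitting delegate to scikit-learn; the FDL core, the dense
baseline and their trainer are this package's own numpy implementation.

## Evaluation

Per-class metrics use the one-vs-rest reduction of the 6×6 confusion
matrix. When a class is absent from both truth and prediction, precision,
recall and F1 are reported as 0 (the convention visible in published
per-class tables, where an empty class prints 0.00) and specificity
degenerates to 1. "Accuracy" per class is one-vs-rest binary accuracy —
the only reading under which six different per-class accuracies coexist
with a single overall accuracy (the trace of the confusion matrix over n).
ROC curves sweep all score thresholds (ties grouped), so trapezoidal AUC
equals the Mann–Whitney pair statistic with ties counted one half; the
test suite checks this identity against brute-force pair enumeration.
Cohort summaries print counts and half-up one-decimal percentages.

## Synthetic cohorts

`generate_cohort` draws the 15 predictors from the published marginal
frequencies with two internal-consistency constraints: lymph-node
metastasis is positive exactly when pN > N0, and TNM stage follows an
AJCC-7-style lookup on (T, pN) mapped onto the published TNM marginal by
ordinal quantile coupling. The coupling is needed because a hard lookup is
arithmetically incompatible with the published table (it prints 9 stage-IVb
patients but only 3 T4b + 5 N3) and would distort stage marginals by ~5
percentage points; quantile coupling keeps the marginal exact in
expectation while preserving monotone dependence on (T, pN) severity.

Survival is planted through a latent risk score — additive per-level
log-odds contributions of TNM stage, recurrence, distant metastasis,
extranodal extension and margin, centered at the cohort mean — driving a
constant monthly death hazard h = logistic(−4.41 + s·r) (baseline ~0.012/
month, i.e. median survival near five years for an average-risk patient).
Months are the first failure of a geometric clock truncated at 120, which
reproduces the published table's bimodal class profile: many early deaths,
many five-year survivors. At signal strength s = 0 the survival class is
independent of every predictor; mutual information between stage and class
rises monotonically with s. Missingness, when requested, is injected
uniformly over predictor cells (which cells carried missing values in the
real cohort is unknown).

`exact_fixture` reproduces the published table count-for-count: each
variable's column is an exact multiset, shuffled independently per seed,
with months uniform within each record's class interval. Its joint
distribution across variables is synthetic and explicitly not claimed —
passing fixture checks validates the summarizer and the printed marginals,
not any joint structure of the real cohort. Two printed percentages in the
published table are inconsistent with their own counts under any rounding
(241/581 → 41.5 printed 41.4; 67/581 → 11.5 printed 11.6); the package
follows the counts and half-up rounding.

## Desk-scale comparison study

The frozen study conditions are n = 1000 synthetic patients,
signal strength 6.0, no missingness, learning rate 3e-2, batch 32,
patience 12, max 300 epochs, five seeds, identical protocol for the fuzzy
network and its dense twin. Signal 6.0 was chosen from the generator's
information ceiling: at that strength the Bayes-optimal accuracy (computed
from the true per-record hazards) is ~0.82 against a majority-class rate of
~0.42, leaving room for trained models to clear the majority rate by a
wide margin; at signal 3 the ceiling-majority gap (~0.25) would make that
margin unattainable for any classifier.

What passing this study shows — and what it does not: the synthetic risk
is additive on the log-odds scale, exactly representable by both networks,
and free of the measurement noise, coding idiosyncrasies and unrecorded
confounders of real medical records. Under these clean conditions the
fuzzy network and its dense twin converge to statistically indistinguishable
accuracies (~0.07 below the Bayes ceiling), and their per-seed ordering on a
200-record test split is dominated by sampling noise; the large
fuzzy-vs-plain gap reported on the private clinical cohort is not expected
to — and does not systematically — reappear here. The fuzzy network does
show the best mean one-vs-rest AUC of the four models in the shipped
acceptance run.

## Known limitations

* No censoring; the >60-month class absorbs all long survivors.
* The generator's joint predictor distribution is independent draws apart
  from the two consistency constraints; real cohorts correlate grade,
  invasion and stage.
* Rule antecedents are fixed after initialization; only MF parameters and
  consequents train.
* The SVM exposes uncalibrated decision values, so its AUCs are comparable
  within the model but its scores are not probabilities.
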
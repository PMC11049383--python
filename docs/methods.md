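# Methods

This note records the modelling choices behind `drscreen`: the induction
algorithm, the numerical conventions, the synthetic-data model, and the
places where the design was genuinely open and a decision had to be made.

## Fuzzy partitions

Each continuous predictor is covered by trapezoidal fuzzy sets in Ruspini
configuration: breakpoints are placed at evenly spaced cohort quantiles
(k + 1 breakpoints for k sets, default k = 3: low / medium / high), and
each interior breakpoint becomes a linear crossover zone of half-width 0.25
times the smaller neighbouring gap. Adjacent flanks mirror one another, so
memberships sum to exactly 1 everywhere in the observed range; the outermost
sets are closed (membership 1 at the range ends). Categorical and boolean
predictors get one crisp singleton set per level, making fuzzification the
identity one-hot encoding in the crisp limit.

Quantile knots, rather than equal-width bins, keep branch evidence masses
comparable under the skewed clinical marginals (microalbuminuria in
particular). The number of sets is configurable per attribute; three was
chosen as the smallest partition that distinguishes "low / typical / high"
clinical readings. Duplicated quantiles (heavy ties) collapse the affected
sets; a constant attribute degenerates to a single set with a warning.

At prediction time, values outside the training range are clamped to the
nearest range edge, so an out-of-range patient loads the outermost set with
membership 1 instead of vanishing from every branch. Partitions are frozen
at training time and serialised inside the model file, so prediction always
uses training-cohort quantiles.

## Tree induction

Trees follow the Yuan–Shaw cognitive-uncertainty scheme. With evidence
weights w (one per training record, initialised to 1) and crisp class
memberships c_k:

- subsethood S(w, c_k) = Σ min(w, c_k) / Σ w;
- the class possibility distribution is π = S / max_k S;
- node ambiguity is g(π) = Σ_i (π*_i − π*_{i+1}) ln i with π* sorted
  descending (0 for a pure node, ln 2 for a perfectly ambiguous binary
  node);
- a candidate attribute's score is the branch-mass-weighted mean ambiguity
  over its fuzzy sets, with branch evidence w_j = min(w, μ_j) (product
  combination available as a config option).

At each node, min(m, remaining) attributes are drawn without replacement
from those not yet used on the path (fuzzy sets cover an attribute's whole
range, so path reuse adds nothing); the drawn candidate with the lowest
score wins. Scores within 1e-12 of each other are treated as ties and
resolved lexicographically — cross-implementation float noise would
otherwise make mathematically tied scores order-dependent.

A branch becomes a leaf when the dominant class subsethood reaches the leaf
threshold τ, when no attributes remain, or when its evidence mass falls
below 1e-6 (such vacuous leaves inherit the parent majority). Leaves store
the dominant class and its subsethood as truth degree. Class ties at a
node resolve to the with-risk class: a tie sends the patient to screening
sooner. An optional significance α-cut (default 0, i.e. disabled) zeroes
memberships below the cut before combination.

## Forest, voting, certainty

Each tree trains on an independent bootstrap resample (disable with
`bootstrap=False`); per-tree random streams derive from (seed, tree index),
so trees are reproducible individually and the ensemble's prefix is stable
when T grows. Classification propagates a record down every positive-mass
branch, accumulates per-class support as Σ(path mass × leaf truth) over
reached leaves, and normalises to the tree's vote. The forest averages
tree votes equally (certainty-weighted voting is a config option); the
label is the argmax, exact vote ties go to with-risk, and the winning vote
mass — always ≥ 0.5 in the binary case — is the reported certainty degree.

## Model selection

Stratified k-fold assignment (scikit-learn `StratifiedKFold`, shuffled,
seeded) is computed once and shared by every grid configuration, making
comparisons paired; the SHA-256 of the assignment vector is exposed so
pairing can be audited. Stratification matters at the ~15% outcome
prevalence these cohorts show. The selection rule maximises mean accuracy
with ties broken by sensitivity then specificity; the full long-format fold
table is exported so any other rule can be re-applied. A subsample
fraction lets the 132-configuration default sweep run at desk scale.

## Screening statistics

All ratios are exact count ratios; F1 is computed from full-precision
precision and recall. Zero-denominator metrics are reported as
not-applicable, never as 0 or 1. AUC uses the Mann–Whitney rank
formulation with average ranks (ties count half), identical to trapezoidal
ROC area. Binomial confidence intervals use the Wilson score method
(robust at extreme proportions); the AUC interval uses the Hanley–McNeil
standard error. FP/(TP+FP) and FN/(FN+TN) are reported as positive and
negative false discovery rates; screening literature sometimes calls these
type-1/type-2 error rates, and the complements of PPV and NPV recover them
exactly.

## Synthetic cohort model

The generator emulates the marginal structure of a large Spanish
primary-care type-2-diabetes cohort; the real extract is not publicly
deposited.

- Continuous marginals are truncated normals whose *underlying* location
  and scale are solved (two-moment root-finding) so the truncated
  distribution hits the published mean and SD exactly — naïve truncation
  would bias diabetes duration (bound at 0) upward by ≈ 0.6 y. Targets:
  age 68.01 ± 10.41 (18–110), duration 9.11 ± 5.48 (0–60), BMI
  27.86 ± 5.17 (12–70), HbA1c 7.75 ± 1.59 (3.5–19), eGFR 75.08 ± 16.55
  (1–160).
- Microalbuminuria (25.44 ± 125.92 mg/24 h; SD ≫ mean) cannot be Gaussian.
  It is a mixture: 85% uniform on the normal range 0–30 mg, 15% log-normal
  tail with parameters moment-matched so the mixture reproduces the target
  mean and SD.
- Age and eGFR are coupled through a Gaussian copula at ρ = −0.4
  (filtration declines mechanically with age); other covariates are
  independent.
- Categoricals: 57% male; treatment 9.8% diet / 76.7% oral / 13.5% insulin
  (the published three-level breakdown; a four-level option splits out
  insulin analogues); 30.9% uncontrolled hypertension; 7.64% baseline mild
  DR.
- Outcomes: any-DR from a logistic model on standardised covariates; the
  referable-DR model is evaluated only among any-DR positives, so the
  label hierarchy holds by construction. Intercepts are calibrated by
  bisection against the drawn cohort's realised label fraction (targets
  15.5% any DR, 4.77% referable DR).
- Default effect sizes (log-odds): HbA1c +1.5/SD, duration +1.0/SD,
  baseline mild DR +3.0, insulin use +0.75, eGFR −0.5/SD. These are
  package choices, not published estimates, sized so the true linear
  predictor discriminates at AUC ≈ 0.89 — comparable to the AUC the
  emulated deployed system reports on its real cohort — leaving the gap to
  a trained forest attributable to the classifier, not to an
  unlearnable outcome.

What the generator does **not** emulate: longitudinal visit structure,
informative missingness, correlations among metabolic covariates beyond
age–eGFR, regional treatment patterns, or the real cohort's
covariate-outcome dependence. Passing tests therefore demonstrate
correctness and sane statistical behaviour of the pipeline, not clinical
performance on real EHR data; the published real-cohort AUCs (0.93 any DR,
0.90 referable DR) are not reproducible from synthetic data and are not
claimed.

Test fixtures: `tiny_crisp` is a 12-record hand-solvable cohort whose
outcome is `mild_dr OR (uncontrolled hypertension AND insulin)` with all
continuous predictors constant (the exact rows are in
`drscreen.simulate.TINY_CRISP_ROWS`); `separable` gives positives HbA1c
9–11 and negatives 5–7 (margin 2, so any sensible classifier reaches AUC
1); `null_signal` draws default covariates with an independent coin-flip
outcome; `overlap_midpoints` places values on a uniform grid so partition
crossovers are predictable.

## Risk bands

Certainty of developing DR (the with-risk vote mass, whichever label wins)
is banded at cut-offs 0.30 / 0.50 / 0.70 into normal / low / moderate /
high, mapped to 24 / 18 / 12 / 6 months to next screening. The cut-offs
are package defaults — the deployed system's boundaries are not published —
and are mandatory-visible in `BandConfig`. Boundary values take the
higher-risk band (conservative). Non-high bands are constrained to the
12–36-month extension range appropriate for lower-risk patients; the
6-month high-risk interval intentionally sits below it.

## Problem sizes and numerical conventions

The test suite and acceptance script measure: exact small-n oracles
(n ≤ 20 crisp datasets against brute-force tree induction; exhaustive AUC
pair counting), marginal recovery and prevalence calibration at
n = 100 000, and forest discrimination on a 10 000-patient cohort
(8 000 train / 2 000 test, 50 trees) with a 2 000-patient null control
(20 trees). These sizes give stable estimates (AUC standard error ≈ 0.013
at the main setting) at desk scale. Determinism is exact: a single master
seed drives per-tree substreams, cohort draws, and fold assignment, and
model serialisation uses sorted JSON keys so identical forests are
byte-identical on disk.

## Known limitations

- Binary outcomes only; no multiclass grading of retinopathy severity.
- No pruning, feature importances, or incremental training.
- Membership functions are quantile-placed, not optimised from data.
- Wilson intervals ignore the paired structure when comparing two reports;
  no DeLong test for AUC differences.
- The exclusion policy drops incomplete records (as the emulated screening
  workflow does); there is no imputation path.
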
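# Methods

This note documents the models and procedures implemented in `fairaudit`,
the assumptions behind them, the parameters that matter, and what the test
suite does and does not establish.

## Synthetic cohort generator

The generator emulates the *structure* of a Parkinson's baseline
cross-section, not any individual-level properties of real data.

**Stated world.** Defaults: 648 PD / 434 HC participants; 391 males among
PD and 202 among HC; mean ages 64.23 / 62.83 years; thirteen clinical
features (smell identification, semantic fluency, sleep/mood scales,
UPDRS I–III, Hoehn & Yahr stage, Schwab & England score, education,
fatigue) with published class-conditional means. Class sizes, male counts
within class, and White counts within class are realized by **exact
allocation** (`round(frac · n)` memberships placed at random positions),
so these counts are invariants, not expectations.

**Assumptions and choices.**

- *Feature model*: independent class-conditional Gaussians. The published
  summary gives one spread value per feature without stating whether it is
  a pooled SD or a standardized difference; we treat it as a within-group
  SD with a floor of 0.1 (several printed values are 0.01–0.07, which
  would make features near-deterministic class labels). Configurable per
  feature.
- *Age*: Gaussian per class (SD 9 years, configurable), truncated to
  [30, 95]. Only the class means are published.
- *Race*: no counts are published beyond "skewed toward White"; default
  90% White within each class, configurable.
- *Missingness*: completely at random, per feature, default rate 0.05 —
  a modest observational-study level; no mechanism is published.
- *No inter-feature correlation* beyond what the shared class label
  induces, and no longitudinal visit structure: this is a single-visit
  cross-section.

A green test on this world therefore establishes pipeline correctness
(counts, formulas, scopes, reproducibility) — it does not establish that
effect sizes transfer to the real cohort, whose feature correlations,
missingness mechanism and race composition are unknown here.

**Planted outcome bias.** `plant_outcome_bias` relabels a minimal random
subset so that P(y=1 | unprivileged) − P(y=1 | privileged) equals a chosen
value while preserving the total positive count (the target group rates
solve the two-equation system exactly; rounding error is at most one
sample per group). By default the relabeled rows' clinical features are
also redrawn from their new class-conditional distribution. This matters:
with label-only flips the feature distribution per group is unchanged, so
a classifier that never sees sensitive attributes *cannot* express the
planted disparity and prediction-level SPD stays at its skew-driven
baseline. Redrawing makes the planted disparity learnable, which is the
point of planting it. `resample_features=False` restores pure relabeling.

## Preprocessing

Fixed order: clean → missingness filter → split → impute → min–max
normalize → binarize sensitive attributes. Contracts:

- duplicate rows: first kept, order preserved; numeric-like text coerced,
  uncoercible cells become missing;
- a feature is dropped only when *strictly more* than 30% of its cells are
  missing (a feature at exactly the threshold survives);
- imputation: median (numeric) / mode with smallest-value tie-break
  (categorical), fitted on training rows only by default
  (`fit_scope="all"` reproduces the laxer reading in which statistics see
  all rows — the source procedure does not state which was used);
- normalization: y′ = (y − y_min)/(y_max − y_min) · (d − c) + c with
  [c, d] = [0, 1], fitted on training rows; out-of-range test values are
  clipped and counted; a constant feature maps to c;
- split: stratified-by-label 80/20 holdout plus 5 stratified CV folds in
  the training portion, all reproducible under one seed. 20% of 1,082 is
  216.4, so 217 rows are held out (ceiling), within rounding of the
  stated fraction.

Sensitive attributes (age, gender, race, and their binarized group
columns) never enter the model-facing feature view; an injected leakage
proxy deliberately does. Default binarizations: age cut at 60 years
(privileged = under 60, matching the predominance of 60+ patients), race
White vs Non-White (privileged = White), gender male/female (privileged =
male). All three are configurable `SensitiveSpec`s.

## Feature selection

Two stages, both operating on training rows only and never on sensitive
columns:

1. *Correlation pruning*: among every feature pair with |Pearson r| above
   0.70 (configurable), the member with lower mutual information with the
   label is removed, highest-correlation pair first; ties keep the earlier
   column. Lowering the ceiling can only remove more, never fewer,
   features.
2. *Recursive importance*: up to 3 rounds of gradient-boosted importance
   ranking keep the top 75% each round; the final set is the features
   retained in every round (the keeps are nested, so this is the last
   round's set). The boosting learner is scikit-learn's
   `GradientBoostingClassifier`; its impurity-gain importances play the
   role of gain importance in the original boosted-tree formulation.

No correlation ceiling, round count or keep fraction is published; the
defaults above are package choices exposed in the API.

## Metrics

All bias metrics are signed unprivileged-minus-privileged, recorded in
every report. The defining AAOD formula is a nonnegative magnitude, yet
signed values are what practitioners compare across conditions; we report
sign(ΔTPR) · magnitude (falling back to sign(ΔFPR) when ΔTPR = 0, so a
zero report still means equalized odds) and store the plain magnitude
alongside. Any rate with an empty denominator is NaN — never silently 0 —
and aggregation reports how many entries it skipped. The leakage
diagnostic Δerror = |E[L | g=1] − E[L | g=0]| supports 0–1 loss (where it
equals the between-group accuracy gap) and cross-entropy.

## Optimized pre-processing mitigation

The transformation domain is a finite outcome space: the k = 3 first
model-facing features (configurable; intended to be the top selected
ones) quantile-binned into 4 bins each, crossed with the binary label.
For each group s and each observed source (x, y), the map gives a
distribution over target outcomes (x̂, ŷ). The LP minimizes expected
distortion Σ π_s p̂(x,y|s) p(x̂,ŷ|x,y,s) Δ, with Δ = Hamming distance on
bin coordinates + 2 · [label flipped], subject to:

- fairness: |P(ŷ=1|s=1) − P(ŷ=1|s=0)| ≤ ε (default 0.05) under the
  transformed distribution;
- per-source distortion: E[Δ | x,y,s] ≤ 0.5 (default);
- fidelity: TV(transformed, original (x,y) marginal) ≤ 0.1 (default).

Numerical choices: HiGHS solver; solutions are clipped at 0 and
row-renormalized; constraint checks in tests allow 1e-4 slack over the
1e-6 solver tolerance. An infeasible program raises a structured error
carrying the minimal feasible ε found by bisection (resolution 1e-3). A
distribution already satisfying the fairness bound admits the identity
map at zero cost, and because every off-diagonal move has positive cost,
a zero objective *implies* the identity — the LP cannot silently shuffle
mass. Tightening ε can only grow the optimum (feasible-set nesting).

Applying the map samples one target outcome per training row; moved
features are realized as the target bin's median, features whose bin did
not change keep their raw values (so the identity map is a no-op on the
data, not just in distribution). Rows whose (cell, label) combination was
unseen for their group are routed through the nearest observed source and
counted. Test rows are never transformed.

k defaults to 3 rather than 4 because the outcome space (and LP) grows
multiplicatively in bins^k: at k = 4 a single solve takes ~13 s against
~0.5 s at k = 3, with identical optima on default cohorts — the larger
map buys nothing here while breaking interactive use and the repeated-run
recovery checks.

**What "recovered" means.** The LP certifies the fairness bound for the
*transformed distribution* (the map's implied per-group positive rates).
The sampled training labels then deviate from the implied rates by
binomial noise (~0.03 at n ≈ 865), so recovery is asserted at the
distribution level; a separate law-of-large-numbers test checks the
sampled rates converge to the implied ones at n = 50,000.

## Attacks

*Poisoning*: flips exactly round(rate · n_train) labels. Quotas per
class × group stratum are apportioned by largest remainder, so equal
strata get equal flips and the global count is exact; a stratum smaller
than its quota is capped and the shortfall logged rather than silently
redistributed. Main rate 5%, sweep {0, 5, 10, 15, 20}%; validation and
test labels are byte-identical before and after, asserted in tests.

*Leakage*: adds a binary column agreeing with the sensitive attribute
with probability α = 0.90, independently per row, across **all**
partitions (systemic leakage), injected after preprocessing and before
feature dropping, and retained in the feature view. The realized
agreement is logged.

Seeds: base 4765416; per-fold/per-repeat seeds derive as
base + fold + 1000 · repeat (mod 2³¹).

**A note on direction.** Flipping labels at equal rate ρ inside every
class × group stratum moves each group's base rate p toward ½:
p′ = p(1 − ρ) + (1 − p)ρ, so a between-group gap contracts by (1 − 2ρ).
Models trained on the poisoned labels track the contracted gap, and mean
|SPD| of predictions *falls* with the poisoning rate on these cohorts
(measured: decision-tree |SPD| ≈ 0.13 → 0.07 across the sweep). Widening
fairness gaps under this attack would require group-targeted flipping,
which the indiscriminate scheme implemented here deliberately is not.
The corresponding acceptance assertion (gaps non-decreasing in rate) is
therefore expected to fail on this generator, and is left failing rather
than weakened; accuracy, by contrast, declines monotonically for the
decision tree and in expectation (effect ≈ 0.005 per step, below the
10-seed noise floor) for the random forest.

## Models

Decision tree (depth 10, min leaf 2, Gini), random forest (200 trees,
depth 12, min split 4, sqrt features, bootstrap), and a
d→256→128→1 ReLU perceptron (Adam, lr 1e-3, L2 1e-5, batch 16, ≤100
epochs, early stopping patience 10). Grid search runs over the split
plan's 5 folds with small grids bracketing the final values (depth
{5, 10, 15} / {8, 12, 16}), selecting by mean CV validation log-loss;
`selection="train_loss"` reproduces the literal lowest-training-loss
rule, which invites overfitting and is not the default. The perceptron's
decision threshold maximizes F1 on the first CV fold's validation part.
Class weights are left at None throughout.

The perceptron is scikit-learn's `MLPClassifier`: batch normalization,
dropout, plateau LR halving and AUROC-based early stopping are not
expressible there; the implemented approximation keeps architecture,
optimizer, learning rate, weight decay, batch size, epoch budget and
early-stopping patience. Tree models reproduce exactly under a fixed
seed; the perceptron reproduces within its framework's seeded-mode
guarantees.

Prediction enforces the training schema exactly (column names and order)
and fails loudly otherwise.

## Experiment harness

Each grid cell (model × attribute × mitigation × attack condition) is
repeated 5 times; every repeat regenerates the cohort, resplits, and
derives a fresh seed, so mean ± SD reflects the full pipeline
variability (switchable to a fixed cohort). Mitigation is fitted per
audited attribute on training rows; attacks respect their scope (the
harness asserts the test labels were untouched on every run). Metrics
are always computed on the clean test partition.

Paired t-tests pair per-repeat values by seed. When all paired
differences are equal the statistic is degenerate; we flag it and report
p = 1 instead of ±∞, avoiding spurious significance on deterministic
models. Raw p-values are primary; an optional Benjamini–Hochberg column
is off by default since the source procedure applies no multiplicity
correction.

## Known limitations

- The synthetic world has no inter-feature correlation, a single visit,
  and MCAR missingness; transfer of effect sizes to the real cohort is
  out of scope.
- The mitigation map covers only the k binned features; disparity carried
  by the remaining features is addressed only through label
  transformation.
- The published headline result tables were computed on the restricted
  cohort and contain internally inconsistent group-rate cells; this
  package reproduces the *procedures*, not those cell values.
- Gradient-based evasion attacks, in-processing (adversarial debiasing)
  and post-processing mitigation are out of scope.
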
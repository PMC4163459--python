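# Methods

This note records the model, the numerical conventions, and the design
choices behind `drivermut`, in the spirit of a methods appendix: what the
pipeline computes, why its defaults are what they are, and what the
synthetic benchmarks do and do not demonstrate.

## Problem setting

The unit of analysis is a missense mutation: a single-residue substitution
(protein, 1-based position, wild residue W, mutant residue M) with an
optional driver/passenger label. Drivers are the positive class
throughout. Positions are 1-based in every file and message; a mutation
whose stated wild residue disagrees with the referenced sequence is
rejected at dataset construction rather than silently remapped.

## Feature encoding

**AARC (residue change).** For each property scale s, the feature is
s(W) − s(M). The encoder is antisymmetric under swapping W and M by
construction. The bundled 15 scales combine published hydropathy,
hydrophilicity, accessibility, flexibility, transfer-energy and mass
tables with Grantham's composition/polarity/volume and per-residue
isoelectric points (see `scripts/make_default_tables.py` for provenance).

**SSM (substitution matrices).** The feature is the ordered element
(W, M) of each matrix; symmetry is not assumed. The bundled 51 matrices
are 24 published alignment/exchange matrices (BLOSUM, PAM, Gonnet, and
related families) plus 27 property-derived matrices: for each bundled
scale the negated absolute property step −|s(i) − s(j)| and, for 12
scales, the negated squared step — the same construction as classical
physicochemical distance matrices, oriented so conservative substitutions
score high. Which 15 scales and 51 matrices are used is configuration;
the pipeline's structure depends only on the counts (15 + 51).

**PSS (sequence 2-grams).** The source protein sequence is encoded as 436
2-gram counts: 400 ordered residue pairs over the 20-letter alphabet
(component index 20·i + j, alphabetical order) followed by 36 ordered
group pairs after mapping through the 6-letter alphabet (index
400 + 6·(g₁−1) + (g₂−1)). Raw counts are used, not frequencies (each half
of the vector sums to L−1; a length-normalization flag exists, default
off). A reducer fitted on training data ranks all 436 components by DX
score (configurable to the 400 20-letter components only), keeps the top
30 (ties broken toward the lower component index) and records the
per-component training mean profile x̄. Each sample's PSS block is its 30
selected counts plus the LCC — the Pearson correlation, computed across
the 436 components in the population (n-weighted) closed form, between
its gram vector and x̄ — 31 features. The profile is the mean over all
training samples by default; a class-conditional variant (average of the
two class means) is available by flag. By default grams come from the
wild-type sequence (the mutant differs in at most two of 436 components;
a flag switches to the mutated sequence). The reducer records the sample
ids it was fitted on, which is what makes the leakage guard below
checkable.

**AF (annotated features).** A schema lists the expected annotated
columns and their kinds; the default schema has 14 binary flags and 15
numeric scores (29 features). Missing binary values are absence-coded as
0 and counted in a missingness log; missing numeric values remain NaN
until a `MedianImputer` fitted on training data fills them — principal
axes and trees require complete data, so imputation is an explicit,
train-fitted pipeline stage rather than something encoders do silently.

Assembly concatenates AARC ‖ SSM ‖ PSS ‖ AF with per-feature provenance
tags; the default width is 15 + 51 + 31 + 29 = 126.

## Feature ranking and incremental selection

**DX.** DX = (mean₊ − mean₋)² / (var₊ + var₋) per feature, with sample
(n−1) variances (config-switchable; oracle tests pin the default). A zero
denominator with distinct means scores +∞ and sorts before every finite
score (among themselves by column order); zero numerator and denominator
score 0. Ranking is descending with stable index tie-breaks.

**mRMR.** Columns are discretized to 3 bins at mean ± σ (population σ —
the convention of the classical mRMR software lineage; binary columns
pass through; constant columns collapse to one bin with a warning).
Mutual information is the plug-in estimate on the empirical joint, in
nats (rankings are base-invariant). The greedy ranking runs all N rounds:
the first feature maximizes I(x; class); each later round maximizes
relevance − mean redundancy (MID, default) or relevance / mean redundancy
(MIQ flag; a 1e-12 floor keeps the quotient finite). Ties keep the lower
column index.

**IFS.** For every top-k prefix of a ranking, repeated stratified k-fold
CV accuracy is computed with a fresh classifier per fold; fold splits are
drawn once per repeat and shared across all k, so the curve compares
feature sets rather than split luck. A repeat's accuracy pools its fold
confusion counts; mean and variance are across repeats. The chosen k is
the smallest attaining the maximum mean accuracy (parsimony on ties).

## Rotation forest

Defaults follow the canonical published algorithm: 10 trees; feature
groups of size 3 (a random permutation chunked, so the last group may be
smaller and every feature is in exactly one group per tree); per group, a
nonempty random subset of classes is drawn, 50% of those instances are
removed and the rest bootstrapped, and principal axes are fitted on that
slice. Axes come from an SVD with `full_matrices=True`, which guarantees
a square orthonormal block even when the slice has fewer rows than the
group has features; a slice with fewer than 2 rows is resampled once and
then falls back to an identity block with a warning. The per-group blocks
assemble into a block rotation of the full space and an unpruned Gini
`DecisionTreeClassifier` (scikit-learn) is trained on the rotated data —
a deliberate, documented substitution of the base learner for the
original C4.5. Prediction averages per-tree leaf class distributions;
exact probability ties go to the positive class. All randomness flows
from a single `RotationSpec.seed`. Models persist via a versioned joblib
archive and refuse to load across format versions.

## Evaluation

Metrics are stored as proportions and rendered as percentages only at the
presentation layer. MCC with a zero denominator is defined as 0; a
classifier that never predicts positive has *undefined* precision,
reported as NaN rather than 0 so degenerate models are visible.
Cross-validation pools fold confusion counts within each repeat and
reports mean/variance across repeats (per-fold metric averaging is
flag-controlled); ROC area is the Mann–Whitney rank statistic on pooled
out-of-fold positive-class probabilities, ties counted half.

Two leakage defenses are built in. `evaluate_on_holdout` refuses a test
matrix whose sample ids intersect the PSS reducer's recorded fit samples.
`cross_validate_pipeline` goes further: it refits the reducer and the
imputer inside every training fold and audits the fit-sample/test-fold
overlap. The distinction matters empirically: fitting the 30-gram
selection once on all samples before CV — as single-matrix protocols
effectively do — inflates null-data CV accuracy to ≈0.55 at n = 80,
purely through selection leakage. The leak-free route restores chance
level and is what the null-honesty test uses.

## Synthetic data

The generator emulates a labeled driver/passenger study without external
databases. Proteins are random sequences (default 24 proteins, lengths
80–200); mutations pick a random position, take the wild residue from the
sequence, and draw the mutant residue. Class signal is planted
mechanistically per channel: substitution channels bias drivers toward
large hydropathy changes (weights ∝ exp(effect·|Δkd|/sd)); the sequence
channel gives driver-hosting proteins a first-order within-group
dipeptide preference; the annotated channel shifts three binary rates and
three numeric means. Class balance defaults to 1:1 (the typical curated
train-set design); imbalance and missingness (default AF missing rate
0.1) are configurable.

`effect_size` is defined **once, as the aggregate class separation** of a
planted block: when m features are planted directly, each contributes
effect/√m, so the between-class Mahalanobis distance is effect_size
regardless of m and adding planted features does not trivially saturate
accuracy. This keeps the two recovery benchmarks coherent: per-feature DX
still dwarfs the noise floor for ranking recovery, while CV accuracy
keeps improving until all planted features are included, making the IFS
optimum informative. A fast tabular mode writes feature values directly
(Gaussian columns) for selection/classifier tests where the encoders are
not under test.

What passing these benchmarks shows — and does not. The synthetic
channels exercise every encoder, the ranking methods, the ensemble, and
the evaluation stack end to end, with known ground truth. They do not
emulate mutation recurrence structure, residue-context correlations,
database annotation biases, or the covariate shift between curated
training sets and real screening data; performance numbers on synthetic
cohorts characterize the machinery, not expected accuracy on real tumor
variants.

## Benchmark problem sizes and stability notes

The recovery benchmark uses n = 200 samples with 5 informative of 100
features at aggregate 4σ; the null and calibration checks use 20 seeds of
n = 80–100; the IFS-tracks-complexity check uses a kNN trainer, for which
irrelevant features are genuinely harmful — with tree ensembles the IFS
curve plateaus and its argmax is uniform over the plateau, so the chosen
k is only a stable function of planted complexity when the curve
saturates and the smallest-k tie rule applies. That behavior is a
property of argmax-on-noisy-curves, not of this implementation.

## Known limitations

* The base learner is CART, not C4.5; per-tree behavior differs from the
  original rotation-forest description even though the rotation
  construction matches it.
* The bundled scale/matrix sets are a documented default, not a canonical
  community standard; swap directories of TSVs to change them.
* mRMR discretization (3 bins at mean ± σ) is the lineage convention;
  other binnings change rankings and are not currently implemented.
* The LCC is reported as missing (NaN, with a warning) when either gram
  vector is constant across components — only possible for degenerate
  sequences.
* `simulate` plants signal in hydropathy space for the substitution
  channels; encoders built from scales uncorrelated with hydropathy gain
  little signal, which is realistic but means per-feature recovery rates
  depend on the bundled scale set.
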
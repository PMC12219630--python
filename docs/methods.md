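# Methods

This note documents the models and procedures implemented in `cppsig`,
the parameter defaults and why they were chosen, the numerical and design
decisions taken where the design was genuinely open, what the synthetic
data generator does and does not emulate, and known limitations.

## Sequence parts and coordinates

All coordinates are 1-based and inclusive on both ends (UniProt
convention). An entry is valid iff at least `jmd_len` residues flank the
annotated TMD on both sides; invalid entries are dropped with a logged
reason, never padded. Malformed indices or non-canonical residues raise a
structural error, kept distinct from the short-flank rejection so data
problems are not silently conflated with dataset reduction.

For a TMD of length L, TMD-N is the first ceil(L/2) residues and TMD-C
the remainder. The half-split rule for odd L is a free choice; giving the
extra residue to the N-terminal half is fixed and documented here so
feature identities are stable. TMD-E extends the TMD by `ext_len`
(default 4) residues on each side and is clipped at sequence ends (which
cannot occur for validated entries when `jmd_len >= ext_len`). The
"anchor" is the first four residues of JMD-C — in real membrane proteins
typically basic residues pinning the helix at the interface.

Positional aggregation and plots use a fixed reference frame of
10 + 20 + 10 = 40 residues (JMD-N + TMD + JMD-C with the TMD normalized
to 20 residues); each feature's split is resolved on this frame once.

## The split universe

* Segments: the i-th of n equal chunks for n = 1..15 (120 splits).
  Boundaries are floor((i−1)·L/n)+1 .. floor(i·L/n), which partitions
  1..L for every L; a segment can be empty only when n > L.
* Patterns: 2–4 residues with consecutive gaps of 3 or 4 positions
  (α-helix face periodicity), anchored at either terminus, overall span
  capped at 15 and start offsets filling the cap
  (start + span − 1 ≤ 15). Per terminus: 23 two-residue, 32
  three-residue, and 36 four-residue patterns = 91; both termini: 182.
* Periodic patterns: every 3rd, every 4th, or alternating 3rd/4th
  residue across a whole part, start offsets 1..first-step, both
  termini: (3+4+3+4) × 2 = 28.

Total: 330 splits. C-anchored splits are the mirror image (p → L−p+1) of
their N-anchored twins, returned in ascending order; mirroring is an
involution (property-tested). The enumeration parameters are frozen as
the package's dialect; they reproduce the published counts exactly, which
is the calibration evidence for the dialect. A part shorter than a
split's span yields *not applicable* (NaN), never 0: averaging over zero
residues is undefined, and imputing 0 would fabricate an extreme feature
value. NaN cells are excluded from means, standard deviations, and AUCs.

## Scales

Scales are min-max normalized to [0,1]; constant scales, scales with
missing values, and exact duplicates (after normalization, at 1e-12
resolution) are dropped with counts recorded in the set's provenance.
Redundancy reduction follows the AAclust idea: complete-linkage
agglomerative clustering on 1 − Pearson correlation between the
20-vectors, one representative per cluster (the medoid = highest mean
correlation to its cluster, ties broken by lexicographically smallest
id), with the cluster count k scanned upward from the number of
subcategories until every subcategory of the input is represented. The
scan direction gives the smallest non-redundant covering set. Input row
order does not affect the result (scales are sorted by id first).

## CPP

Defaults: `n_filter=100`, `max_std_test=0.2`, `pct_pre_filter=0.05`,
`max_overlap=0.5`, `max_cor=0.5`, parts = {TMD, JMD-N-TMD-N,
TMD-C-JMD-C}.

Decisions worth recording:

* The pre-filter keeps k = floor(`pct_pre_filter` × features-created)
  features, applied **after** the standard-deviation filter, and the
  selecting quantity is the **absolute** mean difference — feature maps
  retain both signs, so magnitude is what matters for selection.
* The adjusted AUC is the exact rank-sum AUC (ties count 1/2) minus 0.5;
  positive values mean the test set is systematically higher. It is
  antisymmetric under swapping test and reference and verified against
  an all-pairs concordance oracle.
* Ranking ties (equal |AUC|) break by |mean difference|, then feature id,
  so the ranking is total and reruns are byte-identical.
* The redundancy predicate is: positional Jaccard overlap > `max_overlap`
  **and** (same scale subcategory **or** |scale-vector Pearson r| >
  `max_cor`). The conjunction is one consistent reading of "redundant in
  position and scale space"; it is exposed as
  `CPPConfig.conjunctive_redundancy` for the disjunctive alternative.
  Scale correlation uses the absolute value since redundancy is symmetric
  in sign. The greedy scan gives the filter a prefix property: raising
  `n_filter` never removes a previously accepted feature.

## dPULearn

Feature columns are z-standardized before PCA (toggleable). Features
bounded in [0,1] still differ in variance, and PCA is scale-sensitive;
standardization also makes the selection invariant to rescaling any
column. PCA is fit on **all** samples (positives, known negatives,
unlabeled); the retained component count m is the smallest explaining
≥ 80% of variance (overridable as an integer or fraction). Per-component
quotas are allocated proportionally to explained-variance ratio by
largest-remainder rounding with earlier components winning remainder
ties — deterministic and exactly conserving the total. Within a
component, the unlabeled samples with the largest |coordinate − mean
coordinate of positives| are selected (1-D distance per component, not
Mahalanobis, matching the per-component construction); distance ties
break by smaller sample id. The procedure has no random state: ten reruns
produce identical selections, which the suite asserts.

The benchmark harness compares a support vector machine's stratified
5-fold CV balanced accuracy on positives + dPULearn negatives against
seeded uniformly random negative draws, with a two-sided one-sample
t-test of the random draws against the deterministic point value.

## Training harness

The registry mirrors the 10-model-type design by role: decision tree,
random forest, extra trees, and bagged trees (the four tree-flagged
types), logistic regression and SGD-logistic (linear), an RBF SVM with
sigmoid-calibrated probabilities via `CalibratedClassifierCV` (kernel),
a small MLP (neural), and AdaBoost plus gradient boosting
(ensembles). The tree-flagged group is deliberately restricted to models
whose probability output is an average of per-leaf class frequencies, so
the tree-SHAP layer is exactly additive in probability space; boosting
models, whose natural additivity lives in margin space, fill the ensemble
slots instead. Hyperparameter grids are small and frozen in the registry;
feature pre-selection evaluates the configured top-k grid via iterative
importance-based elimination (halving steps re-ranked by a random forest)
with 5-fold CV; when only one (k, parameters) candidate exists the CV is
skipped.

Per round: stratified 80/20 split, selection and fitting on the 80%,
held-out predictions on the 20%. Default 25 rounds × 10 models = 250
final models. Prediction scores for proteins in the training data use
only rounds where the protein was held out (out-of-fold); a protein never
held out (probability 0.8^25 ≈ 0.4% per protein) falls back to all rounds,
flagged in the contribution records. Aggregation across approaches uses
the sample (n−1) standard deviation. Confidence classes: HC substrate
score ≥ 0.8, LC substrate ≥ 0.5, LC non-substrate > 0.2, HC
non-substrate ≤ 0.2 (0.5 classifies as LC substrate).

The relevance score is the mean of five binary factors: new pathway
link, new disease link, mutated TMD-JMD, new protein family, and
dissimilar TMD-JMD (< 30% identity to known substrates).

## SHAP layer

`cppsig.treeshap` implements the exact path-dependent polynomial-time
tree-SHAP algorithm for scikit-learn decision trees, marginalizing
"missing" features by training cover. It is validated against a
brute-force Shapley enumeration over the tree's conditional-expectation
value function (agreement to 1e-10) and is exactly additive:
base value + Σφ = predicted positive-class probability, asserted at
1e-6 per model and sample.

Feature impact for a training protein is its mean SHAP row (across the
tree model types retrained per round on the full training data)
normalized by the sum of absolute values — sign-preserving, idempotent,
Σ|impact| = 1 (all-zero rows are returned unchanged with a degenerate
flag). Feature importance is the mean |SHAP| over samples.

Fuzzy labeling for proteins outside the training data: the protein joins
training with label positive in floor(score × n_rounds) rounds and
negative otherwise. The floor rule reproduces the anchor example of a
0.22 score over 25 rounds mapping to 5 positive rounds (5.5 would round
to 6 under half-up or nearest-even). The positive labels occupy the
first rounds deterministically; round seeds still differ, so schedules
are not degenerate. Both choices are package decisions where the design
was open.

## Synthetic data

The generator emulates the study structure: a small positive class, few
known negatives, and a large unlabeled pool of single-span N-out proteins
with 10-residue JMDs and TMD lengths 19–25. Background TMDs are biased
to hydrophobic core residues (L/I/V/F/A ≈ 74%); JMDs use a mixed
composition with ~11% K/R. Positives carry the planted signature with
per-position probability ε (`effect_size`): K/R anchor, G/A/S TMD-N,
V/I/T cleavage window. By default 20% of the unlabeled pool are hidden
true positives, exercising the positive-unlabeled setting. At ε = 0 the
positive and background residue distributions are identical (verified by
a chi-square two-sample test); at ε = 1 the signature is deterministic.

What the generator does **not** emulate: real TMD length/composition
statistics beyond the hydrophobic bias, sequence redundancy and family
structure (no CD-HIT-like clustering is needed or applied), annotation
noise in TMD boundaries, and any correlation structure between scales
beyond the three planted signal scales. Passing recovery tests therefore
demonstrates that the pipeline detects a planted physicochemical signal
under controlled conditions — not that it would reach the same accuracy
on real proteome data.

## Problem sizes used in the test suite

Recovery properties run at sizes chosen to keep the suite fast while
preserving the study's structure: the 250-model count check trains the
full default harness (25 rounds × 10 models) on a 63+63 planted dataset
with a 30-feature matrix; the 20-seed recovery checks use 63+63 labeled
samples plus 100 unlabeled for CPP (12 scales → 11,880 created features,
40 selected) with a reduced 3-round, 3-model harness, evaluated on a
freshly generated 63+63 dataset so no sample is reused between selection,
training, and evaluation. The planted effect at ε = 1 is strong enough
that the reduced harness is not the binding constraint; at ε = 0 the
fresh-evaluation design keeps the measured balanced accuracy at chance.

## Known limitations

* The AAclust-style selection implements the published coverage
  constraint with a specific medoid and tie-break rule; the reference
  implementation's exact representative rule may differ.
* Pattern/periodic enumeration is one dialect reproducing the published
  counts; the original supplementary enumeration algorithm was not
  available to compare against step by step.
* Tree-SHAP covers only models whose probability is a leaf-frequency
  average; margin-space explanation of boosting models is out of scope.
* The benchmark and recovery thresholds are properties of the synthetic
  conditions; real datasets (with sequence redundancy and annotation
  noise) will generally be harder.
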
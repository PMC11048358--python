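# Methods

## The prediction problem

Pseudouridine (Ψ) is the most abundant internal RNA modification; a "Ψ
site" is a uridine that carries it.  The predictor answers a binary
question: given a fixed-length RNA window centred on a uridine — 21 nt for
human/mouse-style data, 31 nt for yeast-style data — is the centre U a Ψ
site?  Benchmarks in this area are balanced (equal positives and
negatives), and the discriminating signal is largely *positional*:
modified and unmodified windows differ in which nucleotides they prefer at
specific offsets from the centre (e.g. A/U versus C/G immediately 3' of
the centre in human data).

## Architecture

1. **Encodings.**  Each window is represented six ways: one-hot of
   overlapping k-nucleotides (k = 1, 2, 3; dimension 4^k·(λ−k+1),
   position-major blocks, A<C<G<U within a block) and overlapping k-mer
   frequencies (k = 1, 2, 3; dimension 4^k).  One-hot preserves position;
   k-mer frequencies capture composition and deliberately discard it.
   K-mer counts are normalised by λ−k+1 so windows of different lengths
   live on the same scale; the one-hot row sum is exactly λ−k+1 and each
   position block is exactly one-hot, which the tests use as invariants.

2. **Base classifiers.**  Five tree-ensemble families — AdaBoost (ADA),
   gradient-boosted trees (GBDT), XGBoost (XGB), random forest (RF) and
   extra trees (ET) — each fitted to each encoding: 30 (encoding, family)
   pairs.  Hyperparameters are the libraries' standard defaults (100
   estimators); no per-family tuning is attempted, because the
   architecture, not the tuning, is what the package reproduces.  All
   estimators run single-threaded with explicit seeds.

3. **Feature selection (two-step threshold sweep).**  For each pair, the
   family's model is pretrained on the full matrix to obtain per-feature
   importances; the distinct importance values, ascending, are then tried
   as keep-thresholds (keep ⇔ importance ≥ threshold, so candidate masks
   are nested) and each candidate is scored by stratified k-fold CV
   accuracy of a fresh model of the same family.  The best-scoring mask
   wins; ties break toward the larger threshold (fewer features).  Choices
   made where the procedure is underdetermined: the selection metric is
   accuracy (the dominant metric in this literature; the sweep could
   equally rank by MCC), the sweep is cross-validated rather than judged
   on training fit (an all-features mask would otherwise often win
   trivially), and its fold count (default 5) is independent of the
   stacking fold count.  Beyond a cap (default 200) the candidate
   thresholds are subsampled at evenly spaced quantiles, always retaining
   the extremes; the inclusive comparison guarantees a non-empty mask even
   when all importances are zero.

4. **Stacking into the RNA profile.**  The training rows are split into k
   stratified folds (default 10).  For each (encoding, family) pair and
   each fold, the model is fitted on the other folds (masked features) and
   predicts the held-out fold; the collected out-of-fold positive-class
   probabilities form the n × 30 RNA profile.  No profile entry is
   produced by a model that saw that row — the property a brute-force
   refit oracle asserts in the tests.  Masks are selected once on the full
   training data before stacking (the architecture description orders
   selection before classifier construction); a fully nested variant would
   re-run the sweep inside each fold at k times the cost, and the honest
   outer cross-validation below already guards the reported numbers
   against selection leakage.  Probabilities, not hard labels, populate
   the profile: they preserve ranking information for the meta-classifier
   and make per-column correlation diagnostics meaningful.  For new
   sequences, each profile column is the *average* of the k fold-models'
   probabilities; the fold models are therefore retained in the bundle
   rather than refitting a single model on all data.

5. **PSO over profile weights.**  A swarm searches w ∈ [0,1]^30; the
   fitness of w is the stratified k-fold CV accuracy (pooled over folds)
   of a logistic classifier on the column-weighted profile.  Defaults: 60
   particles, 100 iterations, inertia 0.8, cognitive and social factors
   c1 = c2 = 0.6, 10-fold fitness.  The canonical velocity/position update
   is used.  Decisions the canonical description leaves open: velocities
   are clamped to ±0.2 of the unit range (unclamped swarms bounce off the
   box walls), positions are clipped to [0,1] (absorbing walls),
   initial positions are uniform in the box and initial velocities uniform
   in ±vmax, and the CV partition inside the fitness is drawn once per
   search so fitness is a deterministic function of w — otherwise the
   non-decreasing global-best trajectory would be ill-defined under
   resampling noise.

6. **Meta-classifier.**  Logistic regression (lbfgs, max_iter 1000,
   default L2 strength) on the weighted profile, decision threshold 0.5
   (the benchmarks are balanced).  The meta-classifier inside the fitness
   and the final one share settings: the searched weights are only optimal
   for the surface they were scored on.

## Evaluation protocol

ACC, SN, SP and MCC are computed from confusion counts; any metric with a
zero denominator is reported as 0 (balanced data never triggers this, but
degenerate synthetic folds can).  `cross_validate` is deliberately
expensive and honest: outer stratified folds, with feature selection,
stacking *and* the swarm refitted per outer fold.  Metrics are pooled over
all held-out predictions (per-fold sets are also returned; fold-averaged
and pooled values differ only at the third decimal on balanced data).
The unweighted-stacking row ("stack", w = 1) and the PSO row share the
fitted stages within each outer fold — with identical seeds the stages
are identical between modes, so sharing changes runtime only.  A cheaper
`pso_refit=False` variant runs the swarm once on the full dataset and
reuses those weights in every fold; it is explicitly labelled optimistic
(the weights have seen the held-out rows' profile) and is never used for
reported numbers.

## Synthetic data: what it emulates and what it does not

The generator draws each position independently from a class-conditional
distribution: enriched offsets get per-class 4-vectors, all other
positions a common background, and the centre is always U.  The
`human-like` preset (λ=21) puts probability 0.45/0.45 on A/U in positives
and on C/G in negatives at offsets ±1 and ±2 — the near-centre contrast
reported for real human data, with enough redundancy that the Bayes
accuracy (~0.97) comfortably exceeds the recovery bar the tests set.  The
`yeast-like` preset (λ=31) enriches U/G upstream and G/C downstream in
positives.  The `null` preset has no enrichment: both classes are the
same process, so any honest pipeline must score at chance — the control
that would expose information leakage anywhere in the stack.  An optional
first-order blending parameter (`markov`) correlates adjacent bases so
that k = 2, 3 features can carry signal beyond positional marginals.

Deliberately not emulated: real composition statistics, GC bias,
transcript context, redundancy between windows, or any species' actual
motif strengths.  Passing the recovery tests demonstrates that the
machinery extracts a planted positional signal without leaking
information; it says nothing about accuracy on real transcriptomes.

## Problem sizes and the CI profile

`PipelineConfig.fast()` keeps the full 30-column architecture but shrinks
sizes: ADA/GBDT 20 estimators (GBDT depth 2, sqrt feature subsampling),
XGB 30, RF/ET 30; 3-fold sweeps capped at 6 thresholds; 5-fold stacking;
a 10 × 20 swarm with 5-fold fitness.  The recovery experiments in the
tests and the acceptance script use this profile on 200 + 200 windows with
10-fold outer cross-validation — sizes at which the strongly enriched
dataset is far from the decision boundary of the ≥ 0.90 recovery bar, so
the reduction does not soften the checks.  Unit tests use a still smaller
tiny profile (10 estimators, subsets of encodings) since they probe
mechanics, not accuracy.

## Determinism

Every stage seed derives from the single top-level config seed via a CRC
mix (stable across runs and platforms, always < 2^31); all estimators are
single-threaded.  Training twice with the same config reproduces weights,
meta coefficients and predictions bit-for-bit, and a saved bundle
round-trips through disk with identical predictions.

## Known limitations

* Real-data benchmark performance is not reproduced here: the published
  benchmark/independent datasets are distributed through the authors' web
  server rather than an archive, and the base learners' exact
  hyperparameters are unpublished, so numbers on those datasets are not
  derivable from the method description alone.
* The threshold sweep refits a model per candidate threshold; for
  thousands of distinct importances the quantile cap trades optimality
  for tractability.
* PSO is a heuristic: different seeds reach different weight vectors of
  similar fitness, and on easily separable data the swarm frequently
  starts at the ceiling and the fitness curve is flat.
* The generator's positional independence makes one-hot k=1 nearly
  sufficient on default presets; use `markov` > 0 to give higher-order
  features unique signal.
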
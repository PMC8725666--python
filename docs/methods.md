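# Methods

This note documents the models and procedures implemented in `costsense`,
the parameters that matter, the numerical conventions, and the design
choices made where the design was genuinely open.

## Scope and assumptions

The package targets binary classification of continuous-feature data in
the "wide" regime: instances-to-features ratios around 0.004–0.14 and
minority fractions around 5–25%, the regime of gene-expression diagnosis.
The minority class is always the positive class. Multi-class tasks,
missing values and sparse inputs are rejected explicitly rather than
handled approximately: the intended inputs are complete expression
matrices, and silent imputation would change every downstream statistic.

## Feature ranking

All six rankers return a `RankedList`: a permutation of feature indices
with non-increasing scores. Ties are broken by a stable sort, lower
original feature index first, so rankings are exactly reproducible.
Rankings are cut with `cut_ranking`, retaining `ceil(fraction * n)`
features (the product is rounded at 1e-9 before the ceiling so that binary
floating-point artefacts such as `0.1 * 30 = 3.0000000000000004` do not
inflate the cut by one).

**Correlation** uses the weighted Pearson correlation between each feature
and the 0/1 class indicator; features with zero weighted variance score 0.

**Information gain and gain ratio** operate on a supervised
minimum-description-length (MDL) discretization of each feature
(Fayyad–Irani style): recursive entropy-minimizing binary splits, each
accepted only when the gain exceeds
`(log2(N−1) + log2(3^k − 2) − [k·E − k1·E1 − k2·E2]) / N`. All counts,
including N, are *weight sums*, which is what makes an integer-weight run
identical to a run on the instance-replicated dataset. Entropies are in
bits with 0·log 0 := 0. A feature with no accepted cut collapses to a
single bin: IG = 0, and GR = 0 by convention (SplitInfo = 0 there). GR
divides IG by the split information of the induced binning. The MDL
discretizer is implemented here because no installed library provides a
weighted supervised MDL discretization.

**ReliefF** uses every instance as a probe (m = I), Manhattan distance on
range-normalized features, and averages the per-feature differences over
the k nearest hits and k nearest misses (k defaults to 10 and clamps to
the available per-class neighbours; distance ties break by instance
index). The per-feature difference is `|a − b| / (max − min)` with the
range taken over the positively-weighted instances.

*Weighted ReliefF semantics.* Instance weights are interpreted as
replication counts. Weights are normalized to mean 1; each candidate
neighbour then occupies "capacity" u_j among the k neighbour slots, the
probe's own surplus max(u_i − 1, 0) occupies hit slots at distance zero
(standing for its extra copies), and the probe's whole contribution is
scaled by u_i. This is the unique simple semantics under which a run with
mean-1 integer weights is *exactly* the unweighted run on the replicated
dataset, while uniform weights of any scale reduce to classic ReliefF.
The two desiderata — replication fidelity and scale invariance — are
genuinely incompatible without the mean-1 normalization, because
replicating every instance c times changes ReliefF itself (each instance
acquires c−1 zero-distance hits); normalizing first resolves the conflict.
The alternative "scale the update by u_i and search neighbours unweighted"
was rejected because it breaks replication fidelity for any non-uniform
weights.

**SVM-AW / SVM-RFE** fit a soft-margin linear SVM (C = 1 by default) with
per-instance weights normalized to mean 1 (so uniformly scaled weights
give the identical solution; raw scaling would silently rescale the
effective C). Features are standardized internally with weighted moments
before fitting, because |w| is scale-sensitive; the solver tolerance is
tightened to 1e-7 so that scores do not depend on instance order at
ranking precision. SVM-RFE removes `ceil(p% · remaining)` features per
round (minimum 1, so termination is guaranteed; p defaults to 50%),
refits, and records each batch at the tail of the ranking ordered by the
|w| of the round that removed it. With p = 100% the whole ranking comes
from one fit and coincides with SVM-AW. RFE scores are positional
(n, n−1, …, 1) because per-round |w| values are not comparable across
rounds and the `RankedList` contract requires non-increasing scores.

## Cost model

The cost matrix has false-negative cost c = C(+,−), unit false-positive
cost C(−,+) = 1, and zero diagonal (negative "rewards" are rejected).
Two mechanisms derive from it:

- the minimum-expected-cost rule: risks R(+|x) = (1−p)·C(−,+) and
  R(−|x) = p·C(+,−); the predicted label is the argmin, with ties going to
  the positive class — exactly equivalent to thresholding P(+|x) at
  pth = C(−,+)/(C(−,+)+C(+,−)) with ≥ (property-tested on a 101-point
  probability grid for c ∈ {1..5});
- instance weights: raw weight C(+,−) for positives and C(−,+) for
  negatives, rescaled so the total weight equals the number of instances.
  Mass preservation keeps learner hyper-parameters comparable across cost
  settings and makes symmetric costs an exact no-op. Whether a reference
  implementation normalizes this way is not documented anywhere we could
  verify, so exact benchmark reproduction may deviate slightly.

## Classification

The base learner is a 100-tree random forest with ⌊log₂ n⌋+1 split
candidates per node, where n is the *post-selection* feature count (the
selection happens before induction in every strategy). The forest is
delegated to scikit-learn's `RandomForestClassifier`; the contract pinned
by tests is the tree count, the split-candidate count, seeded determinism,
instance-weight support and the probability semantics: P(+|x) is the
average of per-tree leaf class proportions, smoother than raw vote
fractions — which matters because minimum-cost prediction moves the
decision threshold through that probability. In the delegated
implementation non-uniform instance weights act through cost-proportional
bootstrap sampling within bagging (the natural weighting mechanism for a
bagged ensemble); exactly uniform weights are routed through the
unweighted code path so that "all weights equal" is bit-identical to "no
weights" under the same seed.

## Evaluation protocol

Metrics come from confusion counts with the standard degenerate-case
conventions: MCC := 0 when any marginal is zero, F-measure := 0 when
sensitivity + precision = 0, and rates with empty denominators are 0.

Cross-validation is 5-fold stratified, repeated 4 times (20 partitions).
Stratification deals each class's shuffled indices round-robin into folds
(positive class first), so per-fold class proportions match the whole
within rounding and plans are exactly reproducible from the seed.

The Wilcoxon signed-rank test discards zero differences, mid-ranks ties,
and enumerates the exact null distribution of W+ (dynamic programming over
doubled ranks) for up to 25 informative pairs; beyond that it uses the
normal approximation with continuity correction and the standard tie
correction. All-zero differences give p = 1, flagged as degenerate — this
matters in practice because 20 CV runs of near-identical strategies
produce many ties. The implementation is written here (and cross-checked
against scipy on tie-free cases) because scipy's `wilcoxon` silently
switches to the approximation in the presence of ties, whereas the exact
mid-rank policy above is part of this package's contract.

Holm–Bonferroni is the step-down procedure: p-values sorted ascending are
compared with α/k, α/(k−1), …; the procedure stops at the first failure,
so rejections always form a prefix of the significance-ordered list.

## Strategy orchestration

Feature selection is recomputed inside each training fold, never on the
full dataset: ranking, cutting, and weight computation see the training
split only (a poisoning test asserts that sentinel garbage in the test
fold leaves the selection unchanged). One master seed expands into the
plan seed and one forest seed per partition via
`SeedSequence(master, partition_index)`, so whole result tables are
byte-reproducible. At c = 1 all cost-sensitive strategies provably
degenerate to plain feature selection, and the tests assert bit-identical
results there.

## Synthetic data generator

The generator draws Gaussian class-conditional features: d informative
features shifted by δ within-class standard deviations in the positive
class (optionally equicorrelated with parameter ρ through a one-factor
construction), D−d independent noise features, and exact class counts.
The RNG stream is consumed in a fixed order (informative block, noise
block, instance permutation) so that config changes do not silently shift
unrelated draws. Defaults in the test-suite conditions mirror the target
regime: D in the thousands, d a few tens, minority fraction 5–25%, δ
around 1 — hard enough that a cost-blind forest has near-zero sensitivity.

What the generator does *not* model: microarray-specific artefacts such as
batch effects, heavy-tailed intensities, probe-level correlation
structure, or label noise. Passing the synthetic end-to-end tests
therefore demonstrates that the machinery behaves as designed under the
stated statistical model, not that any particular real dataset will show
the same margins.

## Problem sizes and calibrated thresholds

The end-to-end suite uses D = 2,000 features (20 informative, δ = 1) with
10 positives vs 190 negatives over five generator seeds — the package's
chosen benchmark condition for the hybrid-vs-baseline comparison. The
Monte-Carlo assertions (ranker recovery rates, forest sanity bounds, the
hybrid's G-mean margin) were calibrated once by simulation and then frozen
with a safety margin; the calibration values are recorded next to each
assertion.

## Known limitations

- Several upstream defaults of the benchmarks this package emulates are
  undocumented (ReliefF's neighbour count, the SVM regularization
  constant, any feature scaling); the defaults here (k = 10, C = 1,
  internal standardization for the SVM) are reasonable and recorded, but
  exact reproduction of published tables can be sensitive to them.
- Cost-sensitivity at induction time is implemented by weighting, not by
  resampling; with the delegated forest that weighting materializes as
  weighted bootstrap draws.
- Whether rankings "should" be recomputed per fold or once per dataset is
  a protocol ambiguity; per-fold is implemented as the leakage-free
  reading, and it can produce slightly more conservative numbers.
- Binary tasks only; multi-class ReliefF and multi-class costs are out of
  scope.
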
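# Methods

## Problem setting

High-throughput screening (HTS) assays label each tested compound active
(+1) or inactive (−1) against a target. Actives are rare — imbalance
ratios (IR = 100 × minority/majority) in the packaged benchmark manifests
run from 0.26% to 48% — and a classifier trained on the raw data buys
accuracy by drowning the active class in false negatives, or, once
rebalanced naively, precision collapses under false positives. Precision
matters most here: every false positive is a wasted follow-up experiment.
The package implements a precision-aware oversampler (DRAMOTE), four
standard comparator corrections, and the evaluation protocol needed to
compare them honestly.

## The samplers

All oversamplers share one generative primitive: a synthetic minority
point is a convex interpolation `x_a + u·(x_b − x_a)` of two real minority
rows, `u ~ U(0,1)`. Every synthetic point therefore lies inside the convex
hull of the minority class, and every point carries its parent pair and
`u` so it can be reconstructed (to 1e-9) and audited. Given the same
target ratio, every oversampler emits exactly
`N = round(target_ratio × n_majority) − n_minority` points (default
target ratio 1.0, i.e. full balance — the usual choice in the
oversampling literature), which makes the methods comparable point-for-point.

- **RU** keeps all minority rows and subsamples the majority without
  replacement to the target ratio.
- **SMOTE** draws the base uniformly from the minority, the partner
  uniformly from its k nearest minority neighbours (k = 5 by default).
- **MWMOTE** first drops minority rows with no minority member among
  their k1 nearest neighbours (noise), then weights the remaining rows by
  closeness to and density of the borderline majority region, and
  interpolates a weighted-drawn seed with a member of its cluster.
  Defaults k1 = 5, k2 = 3, k3 = ⌈minority/2⌉, Cp = 3, CMAX = 2;
  clustering is average-linkage cut at Cf_th × (mean pairwise minority
  distance), Cf_th = 5. These are this package's documented defaults for
  a method whose original parameterisation leaves several choices open.
- **GSVM-RU** iteratively fits a linear soft-margin SVM (cost 1), extracts
  the negative support vectors as a granule, removes them and repeats
  (T = 3 granules by default); the output keeps all positives plus the
  union of granules — the margin-relevant negatives.

Neighbour searches use Euclidean distance on internally z-scored
features. Whether the original experiments standardized before distance
computation is not documented anywhere we could find; standardization is
this package's convention, chosen so that high-variance descriptors do
not dominate neighbour graphs. Because interpolation is affine, the
choice does not affect the reconstruction invariant. Distance ties break
toward the lowest row index (stable sort), making every sampler
deterministic under its seed.

## DRAMOTE

DRAMOTE modifies SMOTE in three places; each default below is a package
design choice documented here because the method's published description
is qualitative:

1. **Importance weighting.** Minority row i gets selection weight
   `w_i ∝ 1 − p̂_i`, where `p̂_i` is its out-of-fold minority-class score
   from the feedback classifier under internal stratified CV
   (3 folds) on the training partition. High-risk rows (those the
   classifier would lose) get the most reinforcement. If internal CV is
   impossible (minority too small) the majority fraction of the row's
   safe_k-neighbourhood substitutes, flagged. All-equal risks collapse
   to uniform weights. The weighting is monotone: raising `p̂_i` never
   raises `w_i`.
2. **Safe-direction interpolation.** The partner is drawn uniformly from
   the base row's *safe* k nearest minority neighbours — those whose own
   safe_k-neighbourhood (safe_k = 5, over all training rows) has majority
   fraction ≤ θ (default 0.5). If none qualify, the least-overlapped
   neighbour is used and flagged. `u` stays U(0,1): nothing in the
   method's description constrains the position along the segment, only
   its direction.
3. **Feedback loop.** Points are generated in 5 rounds of ≈ N/5. Each
   round's candidate batch is accepted iff the feedback classifier,
   trained on the (inner) training split plus all accepted synthetics,
   does not drop the configured validation metric (precision by default;
   any metric in the suite plugs in) below the incumbent minus a
   tolerance (default 0). After R = 5 rejected resamples the
   best-scoring batch seen is accepted, so each round costs at most
   R + 1 evaluations and the loop always terminates. The validation
   split is a stratified 25% of the training partition, carved before
   any oversampling; the outer test fold is never touched.

The feedback classifier defaults to the classifier being benchmarked
(pairing — "contribution to precision" is classifier-specific) inside the
benchmark harness, and to KNN in standalone use. SVM members supply
continuous scores through a logistic squash of their decision values;
probability-capable members use their probabilities directly.

Setting θ = 1, uniform importance and R = 0 provably reduces the
generative law to SMOTE's; the test suite verifies the reduction
distributionally (two-sample KS on `u` and parent indices over 2,000
draws).

**Randomness discipline:** one `numpy` Generator seeded from the sampler
config drives a call; per batch the stream is consumed as (parent draws,
partner draws, u draws), making outputs byte-reproducible.

## Evaluation protocol

Stratified 5-fold cross-validation (stratification is this package's
choice: at IR below 1% unstratified folds risk zero-minority test sets).
Inside each cell the order is fixed: split → fit the standardizer on the
training fold → apply the imbalance correction to the training fold only
→ fit the classifier → score the untouched test fold. Each fitting step
logs the original row indices it saw; the leakage audit asserts the
intersection with the test fold is empty in every cell.

The roster is SVM-linear, SVM-RBF (default cost and kernel width),
KNN (K = 3), LDA, Gaussian naive Bayes, and a seeded 500-tree random
forest (forest size is a package default; only K and the SVM defaults are
prescribed by the protocol the package follows). One dataset yields
5 × 6 × 5 = 150 cells; nine give 1,350.

Metrics: sensitivity, specificity, precision, G-mean, F1, F0.5 and
rank-sum ROC AUC. G-mean defaults to √(sensitivity × specificity); a
`gmean_variant="product"` flag exposes the bare product for
compatibility with sources that print the formula without the radical.
Any 0/0 ratio (e.g. precision with no predicted positives) propagates as
an explicit undefined marker, serialises as null, and is excluded from
averages with an exclusion count — never coerced to 0, which would
otherwise bias zero-TP folds.

Ranking: per classifier, methods are ranked by their mean metric over
folds and datasets (rank 1 = best; ties break by higher mean precision,
then name — some tie rule is needed to keep ranks integral, and
precision-consistency matches the package's emphasis); ranks are then
averaged over classifiers, lowest average = best method.

Significance: one-way ANOVA across methods on fold-level metric values
(the finest-grained unit available), followed, when p < α, by all-pairs
Tukey HSD at the same α. ANOVA and Tukey come from scipy/statsmodels;
the suite pins them against two hand-computed worked examples.

## Synthetic data

`gaussian_imbalance` draws the minority from N(μ, σ²I) and the majority
from N(0, σ²I) with ‖μ‖ = separation·σ, exact class counts, seeded. It
emulates the minority/majority structure and overlap of real assay data,
not its chemistry: real fingerprint features are binary, correlated and
high-dimensional (a Bernoulli-fingerprint mode with per-class bit
probabilities is provided for that flavour), and real actives are
multi-modal. Passing tests on these generators validates the mechanics
and the directional behaviour of the samplers; it does not certify
performance numbers on any real assay.

The validation experiment ("precision ordering") uses 50 actives vs
2,500 inactives in 10 dimensions at separation 1.5 — a 2% IR, heavy
overlap regime where naive oversampling visibly inflates false
positives — over 20 seeds × 6 classifiers with a stratified 75/25
train/test split per seed (the acceptance script runs the same experiment
at 6 seeds; the per-seed × classifier table is what both aggregate).
Expect mean held-out precision of DRAMOTE ≥ SMOTE; individual
seed × classifier cells can go either way.

## Ensemble screening

`train_ensemble` corrects the training set once (DRAMOTE by default),
fits all six members on the identical corrected matrix, and maps member
outputs to [0,1] — probabilities pass through, margins are min-max
calibrated over the training scores. The ensemble score is the
unweighted mean (median and vote-fraction are configurable; a continuous
[0,1] score table is consistent with averaging, and the published
description does not fix the rule). `top_n` sorts score-descending with
identifier-ascending tie-breaks. The SMILES featurizer is an optional
RDKit hook (Morgan bits); the descriptor pipeline behind real screens is
out of scope.

## Numerical and degenerate-input choices

- Constant features standardize to exact zeros (scale 1), not NaN.
- Parent-pair reconstruction tolerance: 1e-9 (absolute).
- `rankdata` mid-ranks give AUC its Mann–Whitney tie handling.
- Samplers raise a named error below two minority rows; RU flags
  saturation instead of erroring when asked for more majority rows than
  exist; GSVM-RU flags early stop when negatives are exhausted.
- An undefined feedback-validation metric counts as score 0 for the
  accept decision (flagged): a batch that drives the classifier to
  predict no positives should not look acceptable.

## Known limitations

- The exact published internals of DRAMOTE (importance formula, batch
  schedule, acceptance rule) are not publicly documented; this
  implementation realises the described mechanism with the defaults
  above, and its numbers on real assays will differ from the published
  tables, which additionally depend on a 2,940-feature chemistry
  pipeline this package does not reproduce.
- Comparator parameters (MWMOTE, GSVM-RU) are likewise package defaults,
  not confirmed settings of the original comparison.
- The feedback loop's cost scales with rounds × retries × classifier fit
  time; with the 500-tree forest it dominates a benchmark run.
- No cost-sensitive or ADASYN/Borderline-SMOTE baselines; no
  precision-recall-curve AUC.
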
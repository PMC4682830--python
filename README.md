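# dramote

Precision-aware minority oversampling for imbalanced high-throughput
screening (HTS) data, with the comparator corrections and the
benchmarking protocol needed to evaluate it.

## The problem

An HTS assay labels each screened compound active (+1) or inactive (−1)
against a biological target. Actives are rare: imbalance ratios
(IR = 100 × n_active / n_inactive) in the packaged benchmark manifests
range from 0.26% to 48%. Models trained on such data either ignore the
active class or, after naive rebalancing, flood their predictions with
false positives — and in virtual screening every false positive is a
wasted wet-lab experiment, so **precision** is the metric that matters.

## The method

DRAMOTE generates synthetic actives by convex interpolation
`x_a + u·(x_b − x_a)` between real minority rows (as SMOTE does), but:

- the base point `x_a` is drawn with probability ∝ `1 − p̂_i`, where
  `p̂_i` is the out-of-fold minority score of a feedback classifier —
  actives at risk of misclassification get the most reinforcement;
- the partner `x_b` comes only from *safe* nearest minority neighbours
  (neighbourhood majority fraction ≤ θ), steering interpolation away
  from the class-overlap region instead of into it;
- batches of synthetic points are accepted or rejected by a feedback
  loop that refuses any batch that drops the classifier's validation
  precision (any metric of the suite can steer the loop).

The package also provides RU, SMOTE, MWMOTE and GSVM-RU under the same
sampler contract (equal synthetic counts, parent-pair provenance, seeded
determinism), the imbalance metric suite (sensitivity, specificity,
precision, G-mean, F1, F0.5, rank-sum ROC AUC with explicit undefined
handling), stratified leakage-audited 5-fold benchmarking with
per-classifier rank averaging and ANOVA + Tukey significance analysis,
Gaussian/fingerprint simulators, and a six-classifier ensemble
virtual-screening scorer. See `docs/methods.md` for the full model
description and defaults.

## Worked example

```python
import numpy as np
from dramote import (SimSpec, gaussian_imbalance, SamplerConfig,
                     FeedbackConfig, smote, dramote_oversample)

data = gaussian_imbalance(SimSpec(n_minority=20, n_majority=100,
                                  dimension=5, separation=2.0, seed=1))
cfg = SamplerConfig(seed=13)                       # target ratio 1:1
out_s, batch_s = smote(data, cfg)
out_d, batch_d = dramote_oversample(data, cfg,
                                    FeedbackConfig(feedback_classifier="knn"))
print(batch_s.n_points, batch_d.n_points)          # 80 80
err = np.abs(batch_d.reconstruct(data.X) - batch_d.points).max()
print(f"{err:.1e}")                                # 0.0e+00
print(len(batch_d.flags["audit"]))                 # 19
```

Both samplers emit exactly 80 synthetic actives (100 − 20: full
balance), every DRAMOTE point reconstructs exactly from its recorded
parent pair, and the audit log shows the feedback loop's 19 batch
evaluations (5 rounds plus retries) with their validation precisions and
accept/reject decisions.

Benchmarking a grid and ranking methods:

```python
from dramote import run_grid, rank_methods
res = run_grid({"sim": data}, classifiers=("knn", "lda"),
               methods=("ru", "smote"), n_folds=3, seed=0)
print(rank_methods(res, metric="f1").average)
```

A `dramote` console script exposes `simulate`, `balance`, `benchmark`,
`rank` and `screen` subcommands over the same library calls.

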
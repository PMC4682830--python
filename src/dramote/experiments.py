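"""Canned simulation experiments used for validation and reporting.

The precision-ordering experiment probes whether DRAMOTE's safe-direction,
importance-weighted generation buys precision over plain SMOTE on
overlapping imbalanced Gaussians (50 actives vs 2500 inactives in 10
dimensions at 1.5-sigma mean separation — an overlap regime where naive
oversampling inflates false positives).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classifiers import ROSTER, make_classifier, minority_score
from .data import LabeledDataset, apply_standardizer, fit_standardizer
from .feedback import FeedbackConfig, dramote_oversample
from .metrics import compute_metrics, confusion_counts
from .samplers import SamplerConfig, smote
from .simulate import SimSpec, gaussian_imbalance

__all__ = ["precision_ordering_experiment", "DEFAULT_SIM_SPEC"]

DEFAULT_SIM_SPEC = dict(n_minority=50, n_majority=2500, dimension=10, separation=1.5)


def _holdout_split(
    data: LabeledDataset, test_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx, test_idx = [], []
    for label in (-1, 1):
        idx = np.flatnonzero(data.y == label)
        perm = rng.permutation(idx)
        n_test = max(1, int(round(test_fraction * idx.shape[0])))
        test_idx.append(perm[:n_test])
        train_idx.append(perm[n_test:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def precision_ordering_experiment(
    n_seeds: int = 20,
    base_seed: int = 0,
    classifiers: tuple[str, ...] = ROSTER,
    methods: tuple[str, ...] = ("smote", "dramote"),
    sim_spec: dict | None = None,
    test_fraction: float = 0.25,
) -> pd.DataFrame:
    """Held-out test metrics of oversampling methods over repeated draws.

    Per seed: draw the imbalanced Gaussian dataset, hold out a stratified
    25% test split, correct the training split with each method, fit each
    classifier, and record test precision/sensitivity/F1.  Returns the
    flat result table (one row per seed x classifier x method).
    """
    spec_kw = dict(DEFAULT_SIM_SPEC)
    if sim_spec:
        spec_kw.update(sim_spec)
    records = []
    for s in range(n_seeds):
        seed = base_seed + s
        data = gaussian_imbalance(SimSpec(seed=seed, **spec_kw))
        rng = np.random.default_rng(seed + 10_000)
        train_idx, test_idx = _holdout_split(data, test_fraction, rng)
        train, test = data.subset(train_idx), data.subset(test_idx)
        std = fit_standardizer(train)
        train_z = LabeledDataset(apply_standardizer(std, train.X), train.y)
        Zt = apply_standardizer(std, test.X)
        for clf_name in classifiers:
            for method in methods:
                cfg = SamplerConfig(method=method, seed=seed)
                if method == "smote":
                    corrected = smote(train_z, cfg)[0]
                elif method == "dramote":
                    fb = FeedbackConfig(feedback_classifier=clf_name)
                    corrected = dramote_oversample(train_z, cfg, fb)[0]
                else:
                    raise ValueError(method)
                clf = make_classifier(clf_name, seed=seed)
                clf.fit(corrected.X, corrected.y)
                pred = clf.predict(Zt)
                rep = compute_metrics(confusion_counts(test.y, pred))
                records.append(
                    {
                        "seed": seed,
                        "classifier": clf_name,
                        "method": method,
                        "precision": rep.precision,
                        "sensitivity": rep.sensitivity,
                        "f1": rep.f1,
                    }
                )
    return pd.DataFrame.from_records(records)
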
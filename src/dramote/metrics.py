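"""Confusion-matrix metrics for imbalanced binary classification.

Sensitivity, specificity, precision, G-mean, F1, F0.5 and a rank-sum ROC
AUC.  Positives are the +1 (active) class throughout.  Degenerate ratios
(0/0, e.g. precision with zero predicted positives) yield an explicit
undefined marker (NaN) that serialises as null and is excluded from
averages — never silently coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import LabelDomainError, LengthMismatchError

__all__ = [
    "UNDEFINED",
    "is_defined",
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "compute_metrics",
    "fbeta",
    "roc_auc",
    "METRIC_NAMES",
]

#: Marker for metrics whose defining ratio is 0/0.
UNDEFINED: float = float("nan")

METRIC_NAMES = (
    "sensitivity",
    "specificity",
    "precision",
    "gmean",
    "f1",
    "f0_5",
    "roc_auc",
)


def is_defined(value: float) -> bool:
    return not math.isnan(value)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    """The per-evaluation metric vector; NaN marks an undefined entry."""

    sensitivity: float = UNDEFINED
    specificity: float = UNDEFINED
    precision: float = UNDEFINED
    gmean: float = UNDEFINED
    f1: float = UNDEFINED
    f0_5: float = UNDEFINED
    roc_auc: float = UNDEFINED

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def to_json_dict(self) -> dict[str, float | None]:
        """Flat record with metric names as keys; undefined -> null."""
        return {
            name: (v if is_defined(v) else None)
            for name, v in self.to_dict().items()
        }


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=int).ravel()
    bad = set(np.unique(y)) - {-1, 1}
    if bad:
        raise LabelDomainError(f"labels outside {{-1,+1}}: {sorted(bad)}")
    return y


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Count TP/FP/TN/FN with +1 as the positive class."""
    yt = _check_labels(y_true)
    yp = _check_labels(y_pred)
    if yt.shape[0] != yp.shape[0]:
        raise LengthMismatchError(f"{yt.shape[0]} true vs {yp.shape[0]} predicted")
    if yt.shape[0] == 0:
        raise LengthMismatchError("empty label vectors")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        fp=int(np.sum((yt == -1) & (yp == 1))),
        tn=int(np.sum((yt == -1) & (yp == -1))),
        fn=int(np.sum((yt == 1) & (yp == -1))),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else UNDEFINED


def fbeta(precision: float, sensitivity: float, beta: float) -> float:
    """F-beta: (1+b^2) p s / (b^2 p + s).

    beta=1 weighs precision and sensitivity equally; beta=0.5 weighs
    precision twice as much as sensitivity.  Undefined inputs or a zero
    denominator propagate the undefined marker.
    """
    if not (is_defined(precision) and is_defined(sensitivity)):
        return UNDEFINED
    b2 = beta * beta
    den = b2 * precision + sensitivity
    if den == 0:
        return UNDEFINED
    return (1.0 + b2) * precision * sensitivity / den


def compute_metrics(
    counts: ConfusionCounts, gmean_variant: str = "sqrt"
) -> MetricReport:
    """Threshold metrics from a confusion table (AUC is score-based, set
    separately).

    ``gmean_variant`` selects sqrt(sensitivity x specificity) (the standard
    geometric mean, default) or the plain product.
    """
    if gmean_variant not in ("sqrt", "product"):
        raise ValueError("gmean_variant must be 'sqrt' or 'product'")
    sens = _ratio(counts.tp, counts.tp + counts.fn)
    spec = _ratio(counts.tn, counts.tn + counts.fp)
    prec = _ratio(counts.tp, counts.tp + counts.fp)
    if is_defined(sens) and is_defined(spec):
        prod = sens * spec
        gm = math.sqrt(prod) if gmean_variant == "sqrt" else prod
    else:
        gm = UNDEFINED
    return MetricReport(
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        gmean=gm,
        f1=fbeta(prec, sens, 1.0),
        f0_5=fbeta(prec, sens, 0.5),
    )


def roc_auc(scores, y_true) -> float:
    """Rank-sum ROC AUC with mid-rank tie handling.

    Equals the Mann-Whitney statistic: the probability that a random
    positive outscores a random negative, ties credited 0.5.  Returns the
    undefined marker for single-class input.
    """
    yt = _check_labels(y_true)
    s = np.asarray(scores, dtype=float).ravel()
    if s.shape[0] != yt.shape[0]:
        raise LengthMismatchError(f"{s.shape[0]} scores vs {yt.shape[0]} labels")
    n_pos = int(np.sum(yt == 1))
    n_neg = int(np.sum(yt == -1))
    if n_pos == 0 or n_neg == 0:
        return UNDEFINED
    ranks = rankdata(s, method="average")
    rank_sum_pos = float(ranks[yt == 1].sum())
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)
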
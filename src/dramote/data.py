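"""Core data containers and feature-matrix I/O.

The unit every sampler and classifier consumes is a :class:`LabeledDataset`:
a dense numeric feature matrix (one row per compound) with bipolar labels,
``+1`` for active (the class of interest, almost always the minority in HTS
assays) and ``-1`` for inactive.  Dataset manifests summarise assay metadata
and class sizes without carrying the feature matrix itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyClassError,
    LabelDomainError,
    LengthMismatchError,
    MissingLabelColumnError,
    NonNumericFeatureError,
)

__all__ = [
    "LabeledDataset",
    "DatasetManifest",
    "Standardizer",
    "read_feature_csv",
    "write_feature_csv",
    "imbalance_ratio",
    "total_interactions",
    "fit_standardizer",
    "apply_standardizer",
    "invert_standardizer",
]

_VALID_LABELS = frozenset({-1, 1})


@dataclass
class LabeledDataset:
    """Feature matrix plus bipolar labels.

    Parameters
    ----------
    X : ndarray of shape (n_samples, n_features)
        Numeric descriptor values; unitless.
    y : ndarray of shape (n_samples,)
        Labels in {-1, +1}; +1 marks active compounds.
    ids : sequence of str, optional
        Per-row identifiers (e.g. compound IDs).
    meta : dict
        Free-form provenance and warning flags attached by samplers.
    """

    X: np.ndarray
    y: np.ndarray
    ids: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            self.X = np.atleast_2d(self.X)
        self.y = np.asarray(self.y, dtype=int).ravel()
        if self.X.shape[0] != self.y.shape[0]:
            raise LengthMismatchError(
                f"{self.X.shape[0]} feature rows vs {self.y.shape[0]} labels"
            )
        bad = set(np.unique(self.y)) - _VALID_LABELS
        if bad:
            raise LabelDomainError(f"labels outside {{-1,+1}}: {sorted(bad)}")
        if self.ids is not None:
            self.ids = [str(i) for i in self.ids]
            if len(self.ids) != self.y.shape[0]:
                raise LengthMismatchError("ids length does not match labels")

    # -- class structure -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def minority_label(self) -> int:
        """The label of the smaller class; ties resolve to +1 (active)."""
        n_pos = int(np.sum(self.y == 1))
        n_neg = int(np.sum(self.y == -1))
        return 1 if n_pos <= n_neg else -1

    @property
    def majority_label(self) -> int:
        return -self.minority_label

    def mask(self, label: int) -> np.ndarray:
        return self.y == label

    @property
    def minority_mask(self) -> np.ndarray:
        return self.mask(self.minority_label)

    @property
    def majority_mask(self) -> np.ndarray:
        return self.mask(self.majority_label)

    @property
    def n_minority(self) -> int:
        return int(self.minority_mask.sum())

    @property
    def n_majority(self) -> int:
        return int(self.majority_mask.sum())

    def require_both_classes(self) -> None:
        if self.n_minority == 0 or self.n_majority == 0:
            raise EmptyClassError("both classes must be present")

    def subset(self, indices: Sequence[int] | np.ndarray) -> "LabeledDataset":
        idx = np.asarray(indices, dtype=int)
        ids = [self.ids[i] for i in idx] if self.ids is not None else None
        return LabeledDataset(self.X[idx], self.y[idx], ids=ids, meta=dict(self.meta))


@dataclass(frozen=True)
class DatasetManifest:
    """Assay metadata and class sizes (one row of a Table-1-style summary)."""

    name: str
    target_name: str
    minority_size: int
    majority_size: int

    def __post_init__(self) -> None:
        if self.minority_size < 1 or self.majority_size < 1:
            raise ValueError("class sizes must be >= 1")
        if self.minority_size > self.majority_size:
            raise ValueError("minority_size must not exceed majority_size")

    @property
    def total(self) -> int:
        return self.minority_size + self.majority_size


def imbalance_ratio(manifest: DatasetManifest) -> float:
    """Imbalance ratio as a percentage: 100 x minority / majority.

    The ratio of the number of minority active cases to the number of
    majority inactive cases; 0.26 means roughly 1 active per 380 inactives.
    """
    if manifest.majority_size == 0:
        raise ZeroDivisionError("majority_size is zero")
    return 100.0 * manifest.minority_size / manifest.majority_size


def total_interactions(manifests: Iterable[DatasetManifest]) -> int:
    """Sum of all class sizes over a collection of manifests."""
    manifests = list(manifests)
    if not manifests:
        raise ValueError("manifest list is empty")
    return sum(m.total for m in manifests)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_feature_csv(
    path: str | Path,
    label_column: str = "label",
    zero_one_labels: bool = False,
) -> LabeledDataset:
    """Read a labelled feature matrix from CSV.

    One row per compound; all non-label columns become features in file
    order.  Labels must be -1/+1; pass ``zero_one_labels=True`` to remap a
    0/1 scheme (0 -> -1) explicitly — ambiguous schemes are never guessed.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if label_column not in df.columns:
        raise MissingLabelColumnError(
            f"label column {label_column!r} not in {list(df.columns)}"
        )
    id_col = None
    if "id" in df.columns and label_column != "id":
        id_col = df["id"].astype(str).tolist()
        df = df.drop(columns=["id"])
    labels = df[label_column]
    feats = df.drop(columns=[label_column])
    try:
        X = feats.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise NonNumericFeatureError(str(exc)) from exc
    if not np.all(np.isfinite(X)):
        raise NonNumericFeatureError("non-finite feature value")
    y = pd.to_numeric(labels, errors="coerce").to_numpy()
    if np.any(~np.isfinite(y)):
        raise LabelDomainError("non-numeric label value")
    y = y.astype(int)
    if not np.all(y == pd.to_numeric(labels).to_numpy()):
        raise LabelDomainError("fractional label value")
    if zero_one_labels:
        if not set(np.unique(y)) <= {0, 1}:
            raise LabelDomainError("zero_one_labels=True but labels not in {0,1}")
        y = np.where(y == 0, -1, 1)
    bad = set(np.unique(y)) - _VALID_LABELS
    if bad:
        raise LabelDomainError(f"labels outside {{-1,+1}}: {sorted(bad)}")
    return LabeledDataset(X, y, ids=id_col, meta={"feature_names": list(feats.columns)})


def write_feature_csv(
    data: LabeledDataset, path: str | Path, label_column: str = "label"
) -> None:
    """Write a dataset back to CSV losslessly (full float precision)."""
    names = data.meta.get(
        "feature_names", [f"f{i}" for i in range(data.n_features)]
    )
    df = pd.DataFrame(data.X, columns=names)
    df[label_column] = data.y
    if data.ids is not None:
        df.insert(0, "id", data.ids)
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Train-time standardization
# ---------------------------------------------------------------------------

@dataclass
class Standardizer:
    """Per-feature centring and scaling fitted on training rows only.

    ``fitted_rows`` records the row indices the statistics were computed
    from, feeding the benchmark's leakage audit.
    """

    center: np.ndarray
    scale: np.ndarray
    fitted_rows: np.ndarray | None = None


def fit_standardizer(
    train: LabeledDataset, row_indices: Sequence[int] | None = None
) -> Standardizer:
    """Fit centre/scale on a training partition.

    Constant features get scale 1 so they transform to exact zeros rather
    than NaN.  Scale is the population standard deviation.
    """
    if train.n_samples < 2:
        raise ValueError("need >= 2 rows to fit a standardizer")
    center = train.X.mean(axis=0)
    scale = train.X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    rows = np.asarray(row_indices, dtype=int) if row_indices is not None else None
    return Standardizer(center=center, scale=scale, fitted_rows=rows)


def apply_standardizer(s: Standardizer, X: np.ndarray) -> np.ndarray:
    return (np.asarray(X, dtype=float) - s.center) / s.scale


def invert_standardizer(s: Standardizer, Z: np.ndarray) -> np.ndarray:
    return np.asarray(Z, dtype=float) * s.scale + s.center
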
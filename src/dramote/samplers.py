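"""Comparator class-imbalance corrections under one sampler contract.

Four established corrections:

- RU: random under-sampling of the majority class.
- SMOTE: synthetic minority oversampling by interpolation between a
  minority point and one of its k nearest minority neighbours.
- MWMOTE: majority-weighted minority oversampling — synthetic points are
  seeded from "informative" minority samples weighted by how close and
  how crowded the borderline majority region around them is.
- GSVM-RU: granular SVM under-sampling — repeatedly extract the negative
  support vectors of a linear max-margin fit as information granules and
  keep only those negatives.

All oversamplers, given the same dataset and target ratio, generate
exactly the same number of synthetic points, never mutate an original
row, and record per-point parent pairs with the interpolation coefficient
so every synthetic point can be reconstructed and audited.

Neighbour searches use Euclidean distance on internally standardized
features (z-scores of the data handed to the sampler); interpolation is
affine, so points generated in the original feature space reconstruct
identically in either space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist
from sklearn.svm import SVC

from .data import LabeledDataset
from .errors import EmptyClassError, InsufficientMinorityError

__all__ = [
    "SamplerConfig",
    "SyntheticBatch",
    "n_synthetic_points",
    "random_undersample",
    "smote",
    "mwmote",
    "gsvm_ru",
    "METHODS",
]

METHODS = ("ru", "smote", "mwmote", "gsvmru", "dramote")


@dataclass
class SamplerConfig:
    """Shared sampler knobs.

    target_ratio is the desired minority:majority ratio after correction
    (1.0 = full balance).  For oversamplers it fixes the synthetic count
    N = round(target_ratio x n_majority) - n_minority; for RU it fixes how
    many majority rows survive.  ``params`` carries method-specific
    settings (MWMOTE's k1/k2/k3/Cp/CMAX/Cf_th, GSVM-RU's granule count and
    cost).
    """

    method: str = "smote"
    k_neighbors: int = 5
    target_ratio: float = 1.0
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.target_ratio <= 0:
            raise ValueError("target_ratio must be > 0")


@dataclass
class SyntheticBatch:
    """Generated minority points with parent-pair provenance.

    Every point satisfies point = parent_a + u * (parent_b - parent_a)
    where parent_a/parent_b index original minority rows of the input
    dataset and u is the interpolation coefficient in [0, 1].
    """

    points: np.ndarray
    parent_a: np.ndarray
    parent_b: np.ndarray
    u: np.ndarray
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            self.points = self.points.reshape(0, self.points.shape[-1] if self.points.ndim == 2 else 0)
        self.parent_a = np.asarray(self.parent_a, dtype=int)
        self.parent_b = np.asarray(self.parent_b, dtype=int)
        self.u = np.asarray(self.u, dtype=float)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def reconstruct(self, X_original: np.ndarray) -> np.ndarray:
        """Recompute every point from its recorded parents."""
        A = X_original[self.parent_a]
        B = X_original[self.parent_b]
        return A + self.u[:, None] * (B - A)

    @staticmethod
    def empty(n_features: int) -> "SyntheticBatch":
        return SyntheticBatch(
            points=np.empty((0, n_features)),
            parent_a=np.empty(0, dtype=int),
            parent_b=np.empty(0, dtype=int),
            u=np.empty(0),
        )


def n_synthetic_points(n_minority: int, n_majority: int, target_ratio: float) -> int:
    """Synthetic count needed to reach the target minority:majority ratio."""
    desired = int(round(target_ratio * n_majority))
    return max(desired - n_minority, 0)


# ---------------------------------------------------------------------------
# internal helpers
# ---------------------------------------------------------------------------

def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def neighbor_indices(
    query: np.ndarray, pool: np.ndarray, k: int, exclude_self: bool = False
) -> np.ndarray:
    """Indices (into pool) of the k nearest pool rows per query row.

    Distance ties break towards the lowest pool index (stable sort).
    With ``exclude_self`` the identical row position i==j is skipped
    (valid when query IS pool).
    """
    D = cdist(query, pool)
    if exclude_self:
        np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")
    return order[:, :k]


def _append_synthetic(
    data: LabeledDataset, batch: SyntheticBatch
) -> LabeledDataset:
    if batch.n_points == 0:
        return LabeledDataset(
            data.X.copy(), data.y.copy(), ids=list(data.ids) if data.ids else None,
            meta=dict(data.meta),
        )
    X = np.vstack([data.X, batch.points])
    y = np.concatenate([data.y, np.ones(batch.n_points, dtype=int)])
    ids = None
    if data.ids is not None:
        ids = list(data.ids) + [f"synth_{i}" for i in range(batch.n_points)]
    return LabeledDataset(X, y, ids=ids, meta=dict(data.meta))


def _interpolate(
    data: LabeledDataset,
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    u: np.ndarray,
    flags: dict | None = None,
) -> SyntheticBatch:
    A = data.X[parent_a]
    B = data.X[parent_b]
    pts = A + u[:, None] * (B - A)
    return SyntheticBatch(
        points=pts, parent_a=parent_a, parent_b=parent_b, u=u, flags=flags or {}
    )


# ---------------------------------------------------------------------------
# RU
# ---------------------------------------------------------------------------

def random_undersample(
    data: LabeledDataset, config: SamplerConfig
) -> LabeledDataset:
    """Keep all minority rows; subsample majority rows without replacement
    down to the target ratio.  Deterministic under the seed; if the target
    needs more majority rows than exist, all are kept and a saturation
    flag is set."""
    data.require_both_classes()
    rng = np.random.default_rng(config.seed)
    min_idx = np.flatnonzero(data.minority_mask)
    maj_idx = np.flatnonzero(data.majority_mask)
    want = int(round(data.n_minority / config.target_ratio))
    saturated = want >= maj_idx.shape[0]
    if saturated:
        keep_maj = maj_idx
    else:
        keep_maj = rng.choice(maj_idx, size=want, replace=False)
    keep = np.sort(np.concatenate([min_idx, keep_maj]))
    out = data.subset(keep)
    out.meta["sampler"] = "ru"
    out.meta["saturated"] = bool(saturated)
    out.meta["kept_rows"] = keep
    return out


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

def smote(
    data: LabeledDataset,
    config: SamplerConfig,
    n_points: int | None = None,
) -> tuple[LabeledDataset, SyntheticBatch]:
    """Classic minority oversampling by convex interpolation.

    Per synthetic point: a base minority row is drawn uniformly, a partner
    uniformly among its k nearest minority neighbours, and u ~ U(0, 1).
    The random stream is consumed in that fixed order (all bases, then all
    partners, then all u), which makes runs byte-reproducible.
    """
    min_idx = np.flatnonzero(data.minority_mask)
    if min_idx.shape[0] < 2:
        raise InsufficientMinorityError(
            f"need >= 2 minority rows, got {min_idx.shape[0]}"
        )
    if n_points is None:
        n_points = n_synthetic_points(
            data.n_minority, data.n_majority, config.target_ratio
        )
    if n_points == 0:
        return _append_synthetic(data, SyntheticBatch.empty(data.n_features)), (
            SyntheticBatch.empty(data.n_features)
        )
    rng = np.random.default_rng(config.seed)
    Z = _zscore(data.X)[min_idx]
    k = min(config.k_neighbors, min_idx.shape[0] - 1)
    nn = neighbor_indices(Z, Z, k, exclude_self=True)  # positions in min_idx

    base_pos = rng.integers(0, min_idx.shape[0], size=n_points)
    partner_choice = rng.integers(0, k, size=n_points)
    u = rng.random(n_points)
    parent_a = min_idx[base_pos]
    parent_b = min_idx[nn[base_pos, partner_choice]]
    batch = _interpolate(data, parent_a, parent_b, u, flags={"sampler": "smote"})
    return _append_synthetic(data, batch), batch


# ---------------------------------------------------------------------------
# MWMOTE
# ---------------------------------------------------------------------------

def _mwmote_weights(
    Z: np.ndarray,
    y: np.ndarray,
    min_idx: np.ndarray,
    maj_idx: np.ndarray,
    k1: int,
    k2: int,
    k3: int,
    Cp: float,
    CMAX: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Selection weights over the informative minority set.

    Returns (filtered minority indices, informative minority indices,
    selection probabilities over the informative set).
    """
    n_features = Z.shape[1]
    # 1. noise filter: drop minority rows with no minority member among
    #    their k1 nearest neighbours over all rows
    k1_eff = min(k1, Z.shape[0] - 1)
    nn_all = neighbor_indices(Z[min_idx], Z, k1_eff, exclude_self=False)
    # exclude the row itself from its own neighbourhood
    filtered = []
    for pos, i in enumerate(min_idx):
        neigh = [j for j in nn_all[pos] if j != i][: k1_eff]
        if np.any(y[neigh] == y[i]):
            filtered.append(i)
    s_minf = np.asarray(filtered, dtype=int)
    if s_minf.shape[0] < 2:
        return s_minf, np.empty(0, dtype=int), np.empty(0)

    # 2. borderline majority: union of k2 nearest majority rows of each
    #    filtered minority row
    k2_eff = min(k2, maj_idx.shape[0])
    nn_maj = neighbor_indices(Z[s_minf], Z[maj_idx], k2_eff)
    s_bmaj = np.unique(maj_idx[nn_maj.ravel()])

    # 3. informative minority: union of k3 nearest filtered-minority rows
    #    of each borderline majority row
    k3_eff = min(k3, s_minf.shape[0])
    nn_min = neighbor_indices(Z[s_bmaj], Z[s_minf], k3_eff)
    s_imin = np.unique(s_minf[nn_min.ravel()])
    if s_imin.shape[0] == 0:
        return s_minf, s_imin, np.empty(0)

    # 4. information weights: closeness x density of borderline majority
    D = cdist(Z[s_bmaj], Z[s_imin]) / n_features  # normalized distance
    with np.errstate(divide="ignore"):
        inv = np.where(D > 0, 1.0 / D, np.inf)
    cf = np.minimum(inv, Cp) / Cp * CMAX
    row_sum = cf.sum(axis=1, keepdims=True)
    df = np.where(row_sum > 0, cf / row_sum, 0.0)
    sw = (cf * df).sum(axis=0)
    total = sw.sum()
    if total <= 0:
        sp = np.full(s_imin.shape[0], 1.0 / s_imin.shape[0])
    else:
        sp = sw / total
    return s_minf, s_imin, sp


def mwmote(
    data: LabeledDataset,
    config: SamplerConfig,
    n_points: int | None = None,
) -> tuple[LabeledDataset, SyntheticBatch]:
    """Majority-weighted minority oversampling.

    Minority rows whose k1-neighbourhood holds no other minority member
    are treated as noise and excluded.  The remaining minority rows that
    sit nearest to the borderline majority region receive selection
    weights combining closeness to and density of that region (weights
    normalised to sum to 1).  Generation interpolates a weighted-drawn
    informative seed with a uniformly drawn member of its cluster
    (average-linkage clusters of the filtered minority set).  If the
    informative set comes out empty the sampler falls back to plain SMOTE
    with a warning flag.
    """
    data.require_both_classes()
    min_idx = np.flatnonzero(data.minority_mask)
    maj_idx = np.flatnonzero(data.majority_mask)
    if min_idx.shape[0] < 2:
        raise InsufficientMinorityError(
            f"need >= 2 minority rows, got {min_idx.shape[0]}"
        )
    if n_points is None:
        n_points = n_synthetic_points(
            data.n_minority, data.n_majority, config.target_ratio
        )
    p = config.params
    k1 = p.get("k1", 5)
    k2 = p.get("k2", 3)
    k3 = p.get("k3", math.ceil(min_idx.shape[0] / 2))
    Cp = p.get("Cp", 3.0)
    CMAX = p.get("CMAX", 2.0)
    cf_th = p.get("Cf_th", 5.0)

    Z = _zscore(data.X)
    s_minf, s_imin, sp = _mwmote_weights(
        Z, data.y, min_idx, maj_idx, k1, k2, k3, Cp, CMAX
    )
    if s_imin.shape[0] == 0:
        out, batch = smote(data, config, n_points=n_points)
        batch.flags["mwmote_fallback_smote"] = True
        out.meta["mwmote_fallback_smote"] = True
        return out, batch
    if n_points == 0:
        empty = SyntheticBatch.empty(data.n_features)
        empty.flags.update({"sampler": "mwmote", "informative": s_imin, "weights": sp})
        return _append_synthetic(data, empty), empty

    # cluster the filtered minority set (average linkage, distance cut)
    if s_minf.shape[0] > 1:
        pair = pdist(Z[s_minf])
        threshold = cf_th * pair.mean() if pair.size else 0.0
        labels = fcluster(
            linkage(pair, method="average"), t=threshold, criterion="distance"
        )
    else:
        labels = np.ones(s_minf.shape[0], dtype=int)
    cluster_of = dict(zip(s_minf.tolist(), labels.tolist()))
    members: dict[int, np.ndarray] = {
        c: s_minf[labels == c] for c in np.unique(labels)
    }

    rng = np.random.default_rng(config.seed)
    seed_pos = rng.choice(s_imin.shape[0], size=n_points, p=sp)
    parent_a = s_imin[seed_pos]
    parent_b = np.empty(n_points, dtype=int)
    for t in range(n_points):
        pool = members[cluster_of[int(parent_a[t])]]
        parent_b[t] = pool[rng.integers(0, pool.shape[0])]
    u = rng.random(n_points)
    batch = _interpolate(
        data,
        parent_a,
        parent_b,
        u,
        flags={
            "sampler": "mwmote",
            "informative": s_imin,
            "filtered": s_minf,
            "weights": sp,
        },
    )
    return _append_synthetic(data, batch), batch


# ---------------------------------------------------------------------------
# GSVM-RU
# ---------------------------------------------------------------------------

def gsvm_ru(data: LabeledDataset, config: SamplerConfig) -> LabeledDataset:
    """Granular SVM under-sampling.

    Iteratively fit a linear soft-margin SVM on all positives plus the
    remaining negatives, extract the negative support vectors as one
    granule, remove them, and repeat T times.  The returned dataset holds
    every positive plus the union of extracted negative granules — the
    negatives that carried the margin information.  Under-sampling never
    touches a minority row.  If the negatives are exhausted (or a fit
    degenerates) before T granules, iteration stops early with a warning
    flag.
    """
    data.require_both_classes()
    p = config.params
    T = int(p.get("granule_count", 3))
    cost = float(p.get("cost", 1.0))
    if T < 1:
        raise ValueError("granule_count must be >= 1")

    Z = _zscore(data.X)
    pos_idx = np.flatnonzero(data.y == 1)
    remaining = list(np.flatnonzero(data.y == -1))
    granules: list[np.ndarray] = []
    early_stop = False
    for _ in range(T):
        if not remaining:
            early_stop = True
            break
        rows = np.concatenate([pos_idx, np.asarray(remaining, dtype=int)])
        try:
            clf = SVC(kernel="linear", C=cost)
            clf.fit(Z[rows], data.y[rows])
        except ValueError:
            early_stop = True
            break
        sv_rows = rows[clf.support_]
        neg_sv = sv_rows[data.y[sv_rows] == -1]
        if neg_sv.shape[0] == 0:
            early_stop = True
            break
        granules.append(np.sort(neg_sv))
        remaining = [r for r in remaining if r not in set(neg_sv.tolist())]

    kept_neg = (
        np.unique(np.concatenate(granules)) if granules else np.empty(0, dtype=int)
    )
    keep = np.sort(np.concatenate([pos_idx, kept_neg]))
    out = data.subset(keep)
    out.meta["sampler"] = "gsvmru"
    out.meta["granules"] = granules
    out.meta["early_stop"] = bool(early_stop)
    out.meta["kept_rows"] = keep
    return out
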
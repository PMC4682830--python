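"""DRAMOTE: precision-aware minority oversampling with classifier feedback.

Plain SMOTE treats every minority sample as equally worth reinforcing and
interpolates in arbitrary directions, including straight into the region
where the classes overlap — which manufactures false positives.  DRAMOTE
differs in three ways:

1. **Importance weighting.**  Each minority sample's selection probability
   is proportional to its misclassification risk, estimated as
   ``1 - p_hat`` where ``p_hat`` is the out-of-fold minority-class score of
   a feedback classifier trained by internal cross-validation on the
   training partition only.  A minority sample sitting deep inside the
   majority cloud is the one most likely to be lost, so it gets the most
   support.

2. **Safe-direction interpolation.**  The interpolation partner is drawn
   only from the "safe" nearest minority neighbours — those whose own
   neighbourhood is not dominated by majority rows — so new points are
   pushed towards minority-dense regions instead of into the overlap.

3. **A feedback loop.**  Synthetic points are generated in rounds; each
   candidate batch is accepted only if the feedback classifier's
   validation metric (precision by default; any metric in the metric
   suite can be plugged in) does not drop.  After R rejected resamples
   the best-scoring batch seen is accepted, so the loop always
   terminates.

The validation split used by the loop is carved from the training
partition before any oversampling; the outer test fold is never seen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold

from .classifiers import make_classifier, minority_score
from .data import LabeledDataset, apply_standardizer, fit_standardizer
from .errors import InsufficientMinorityError
from .metrics import compute_metrics, confusion_counts, is_defined, roc_auc
from .samplers import (
    SamplerConfig,
    SyntheticBatch,
    _append_synthetic,
    _interpolate,
    _zscore,
    n_synthetic_points,
    neighbor_indices,
)

__all__ = [
    "FeedbackConfig",
    "ImportanceWeights",
    "minority_importance",
    "safe_neighbor_set",
    "feedback_accept",
    "dramote_oversample",
]


@dataclass
class FeedbackConfig:
    """Feedback-loop and safe-region settings.

    feedback_classifier : str or None
        Roster name of the classifier supplying risk scores and batch
        acceptance.  ``None`` means "pair with the classifier being
        benchmarked"; standalone use resolves ``None`` to KNN.
    metric : str
        Validation metric steering batch acceptance (default precision).
    internal_folds : int
        Folds of the internal CV that produces out-of-fold risk scores.
    safe_threshold : float
        theta in [0, 1]: a neighbour is safe if the majority fraction of
        its safe_k-neighbourhood is <= theta.
    safe_k : int
        Neighbourhood size (over all training rows) for the safety check.
    max_retries : int
        R: rejected resamples tolerated per round before the best-seen
        batch is force-accepted.  R = 0 disables the loop entirely.
    acceptance_tolerance : float
        A candidate is accepted if score >= incumbent - tolerance.
    importance_mode : str
        'feedback' (out-of-fold classifier risk), 'neighborhood'
        (majority fraction of the safe_k-neighbourhood), or 'uniform'.
    rounds : int
        Number of feedback rounds; each generates ~N/rounds points.
    validation_fraction : float
        Stratified share of the training partition held out for the loop.
    """

    feedback_classifier: str | None = None
    metric: str = "precision"
    internal_folds: int = 3
    safe_threshold: float = 0.5
    safe_k: int = 5
    max_retries: int = 5
    acceptance_tolerance: float = 0.0
    importance_mode: str = "feedback"
    rounds: int = 5
    validation_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.safe_threshold <= 1.0:
            raise ValueError("safe_threshold must lie in [0, 1]")
        if self.metric not in (
            "precision", "sensitivity", "specificity", "gmean", "f1", "f0_5",
            "roc_auc",
        ):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.importance_mode not in ("feedback", "neighborhood", "uniform"):
            raise ValueError("importance_mode must be feedback|neighborhood|uniform")


@dataclass
class ImportanceWeights:
    """Per-minority-sample selection weights (sum to 1) and provenance."""

    weights: np.ndarray
    provenance: str
    risk: np.ndarray | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        total = self.weights.sum()
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"weights sum to {total}, expected 1")


def _resolve_feedback_clf(config: FeedbackConfig) -> str:
    return config.feedback_classifier or "knn"


def _neighborhood_risk(data: LabeledDataset, config: FeedbackConfig) -> np.ndarray:
    """Majority fraction among the safe_k nearest rows of each minority row."""
    Z = _zscore(data.X)
    min_idx = np.flatnonzero(data.minority_mask)
    k = min(config.safe_k, data.n_samples - 1)
    D = cdist(Z[min_idx], Z)
    D[np.arange(min_idx.shape[0]), min_idx] = np.inf
    nn = np.argsort(D, axis=1, kind="stable")[:, :k]
    return (data.y[nn] == data.majority_label).mean(axis=1)


def _normalize(risk: np.ndarray) -> np.ndarray:
    total = risk.sum()
    if total <= 0:
        return np.full(risk.shape[0], 1.0 / risk.shape[0])
    return risk / total


def minority_importance(
    data: LabeledDataset, config: FeedbackConfig, seed: int = 0
) -> ImportanceWeights:
    """Risk-proportional selection weights for the minority rows.

    ``w_i \\propto 1 - p_hat_i`` with p_hat the out-of-fold minority-class
    score of the feedback classifier under internal stratified CV on the
    given (training) data.  All-equal risks collapse to uniform weights.
    If stratified folds are impossible (minority smaller than 2 folds)
    the neighbourhood majority fraction substitutes for the risk, with a
    warning flag.
    """
    min_idx = np.flatnonzero(data.minority_mask)
    m = min_idx.shape[0]
    if m < 2:
        raise InsufficientMinorityError(f"need >= 2 minority rows, got {m}")

    if config.importance_mode == "uniform":
        return ImportanceWeights(np.full(m, 1.0 / m), provenance="uniform")
    if config.importance_mode == "neighborhood":
        risk = _neighborhood_risk(data, config)
        return ImportanceWeights(_normalize(risk), provenance="neighborhood", risk=risk)

    n_folds = min(config.internal_folds, m, data.n_majority)
    if n_folds < 2:
        risk = _neighborhood_risk(data, config)
        return ImportanceWeights(
            _normalize(risk),
            provenance="neighborhood-fallback",
            risk=risk,
            flags={"fallback": "too few samples for internal CV"},
        )

    std = fit_standardizer(data)
    Z = apply_standardizer(std, data.X)
    clf_name = _resolve_feedback_clf(config)
    p_hat = np.empty(data.n_samples)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    try:
        for tr, te in skf.split(Z, data.y):
            clf = make_classifier(clf_name, seed=seed)
            clf.fit(Z[tr], data.y[tr])
            p_hat[te] = minority_score(clf, Z[te])
    except ValueError:
        # degenerate internal folds (e.g. fewer rows than KNN neighbours)
        risk = _neighborhood_risk(data, config)
        return ImportanceWeights(
            _normalize(risk),
            provenance="neighborhood-fallback",
            risk=risk,
            flags={"fallback": "internal CV failed"},
        )
    risk = 1.0 - p_hat[min_idx]
    return ImportanceWeights(
        _normalize(risk), provenance=f"feedback:{clf_name}", risk=risk
    )


# ---------------------------------------------------------------------------
# safe neighbours
# ---------------------------------------------------------------------------

def _safety(data: LabeledDataset, config: FeedbackConfig) -> np.ndarray:
    """Majority fraction of each minority row's safe_k-neighbourhood."""
    return _neighborhood_risk(data, config)


def _safe_sets(
    data: LabeledDataset, config: FeedbackConfig, k_neighbors: int
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Per-minority-row arrays of safe partner indices (original row ids).

    Returns (safe sets, fallback flags, majority fractions).  Among the
    k nearest minority neighbours of row i, a neighbour is kept if its own
    safe_k-neighbourhood (over all rows) has majority fraction <= theta;
    when all are excluded, the single neighbour with the lowest majority
    fraction is returned and flagged.
    """
    min_idx = np.flatnonzero(data.minority_mask)
    m = min_idx.shape[0]
    if m < 2:
        raise InsufficientMinorityError(f"need >= 2 minority rows, got {m}")
    Z = _zscore(data.X)
    k = min(k_neighbors, m - 1)
    nn = neighbor_indices(Z[min_idx], Z[min_idx], k, exclude_self=True)
    maj_frac = _safety(data, config)  # aligned with min_idx positions
    safe_sets: list[np.ndarray] = []
    fallback = np.zeros(m, dtype=bool)
    for pos in range(m):
        cand = nn[pos]
        safe = cand[maj_frac[cand] <= config.safe_threshold]
        if safe.shape[0] == 0:
            best = cand[int(np.argmin(maj_frac[cand], axis=0))]
            safe = np.asarray([best])
            fallback[pos] = True
        safe_sets.append(min_idx[safe])
    return safe_sets, fallback, maj_frac


def safe_neighbor_set(
    i: int,
    data: LabeledDataset,
    config: FeedbackConfig,
    k_neighbors: int = 5,
) -> tuple[np.ndarray, bool]:
    """Safe interpolation partners for minority row ``i`` (original index).

    Returns the partner row indices and a flag marking the all-unsafe
    fallback (singleton least-overlapping neighbour).
    """
    min_idx = np.flatnonzero(data.minority_mask)
    pos = np.flatnonzero(min_idx == i)
    if pos.shape[0] == 0:
        raise ValueError(f"row {i} is not a minority row")
    sets, fallback, _ = _safe_sets(data, config, k_neighbors)
    p = int(pos[0])
    return sets[p], bool(fallback[p])


# ---------------------------------------------------------------------------
# feedback loop
# ---------------------------------------------------------------------------

def _metric_value(name: str, y_true, y_pred, scores=None) -> float:
    if name == "roc_auc":
        return roc_auc(scores, y_true)
    report = compute_metrics(confusion_counts(y_true, y_pred))
    return getattr(report, name)


def _score_batch(
    batch_points: np.ndarray,
    train_split: LabeledDataset,
    validation_split: LabeledDataset,
    config: FeedbackConfig,
    seed: int,
) -> tuple[float, bool]:
    """Fit the feedback classifier on train + candidate synthetics and
    return (metric on validation, undefined flag)."""
    X = (
        np.vstack([train_split.X, batch_points])
        if batch_points.shape[0]
        else train_split.X
    )
    y = np.concatenate(
        [train_split.y, np.ones(batch_points.shape[0], dtype=int)]
    )
    std = fit_standardizer(LabeledDataset(train_split.X, train_split.y))
    clf = make_classifier(_resolve_feedback_clf(config), seed=seed)
    clf.fit(apply_standardizer(std, X), y)
    Zv = apply_standardizer(std, validation_split.X)
    pred = clf.predict(Zv)
    scores = minority_score(clf, Zv) if config.metric == "roc_auc" else None
    value = _metric_value(config.metric, validation_split.y, pred, scores)
    if not is_defined(value):
        return 0.0, True
    return float(value), False


def feedback_accept(
    candidate_batch: SyntheticBatch,
    train_split: LabeledDataset,
    validation_split: LabeledDataset,
    config: FeedbackConfig,
    incumbent_score: float,
    seed: int = 0,
) -> tuple[bool, float, dict]:
    """Score one candidate batch against the incumbent.

    Trains the feedback classifier on train + candidate points and
    evaluates the configured metric on the validation split (disjoint
    from the training rows by construction).  Accepts iff
    score >= incumbent - tolerance; an undefined validation metric (e.g.
    zero predicted positives) counts as 0 and is flagged.
    """
    validation_split.require_both_classes()
    score, undefined = _score_batch(
        candidate_batch.points, train_split, validation_split, config, seed
    )
    accepted = score >= incumbent_score - config.acceptance_tolerance
    return accepted, score, {"metric_undefined": undefined}


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

def _stratified_holdout(
    data: LabeledDataset, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random split; each class keeps >= 1 row on each side
    where possible."""
    train_idx, val_idx = [], []
    for label in (-1, 1):
        idx = np.flatnonzero(data.y == label)
        perm = rng.permutation(idx)
        n_val = int(round(fraction * idx.shape[0]))
        n_val = min(max(n_val, 1), idx.shape[0] - 1) if idx.shape[0] > 1 else 0
        val_idx.append(perm[:n_val])
        train_idx.append(perm[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def dramote_oversample(
    data: LabeledDataset,
    sampler_config: SamplerConfig,
    feedback_config: FeedbackConfig | None = None,
    n_points: int | None = None,
) -> tuple[LabeledDataset, SyntheticBatch]:
    """Importance-weighted, safe-direction oversampling with feedback.

    Generates exactly the same number of synthetic points as SMOTE would
    under the same target ratio.  Parents are drawn with replacement with
    probability proportional to misclassification risk; partners uniformly
    from the parent's safe neighbour set; u ~ U(0, 1).  Points arrive in
    ``rounds`` batches, each subject to accept/reject control by the
    feedback classifier's validation metric; after R rejections the best
    batch seen is kept.  One seeded generator drives the whole call —
    per batch the stream is consumed as (parents, partners, u) — so runs
    are byte-reproducible.

    The audit trail (``batch.flags['audit']``) records every attempt's
    validation score and decision.
    """
    config = feedback_config or FeedbackConfig()
    data.require_both_classes()
    if data.n_minority < 2:
        raise InsufficientMinorityError(
            f"need >= 2 minority rows, got {data.n_minority}"
        )
    n_total = (
        n_points
        if n_points is not None
        else n_synthetic_points(
            data.n_minority, data.n_majority, sampler_config.target_ratio
        )
    )
    rng = np.random.default_rng(sampler_config.seed)
    clf_seed = int(rng.integers(0, 2**31 - 1))

    feedback_on = config.max_retries >= 1
    if feedback_on:
        inner_idx, val_idx = _stratified_holdout(
            data, config.validation_fraction, rng
        )
        inner = data.subset(inner_idx)
        val = data.subset(val_idx)
        if inner.n_minority < 2 or val.n_minority < 1 or val.n_majority < 1:
            feedback_on = False
            inner, inner_idx = data, np.arange(data.n_samples)
    else:
        inner, inner_idx = data, np.arange(data.n_samples)

    importance = minority_importance(inner, config, seed=clf_seed)
    safe_sets, fallback, _ = _safe_sets(inner, config, sampler_config.k_neighbors)
    inner_min_idx = np.flatnonzero(inner.minority_mask)

    if n_total == 0:
        empty = SyntheticBatch.empty(data.n_features)
        empty.flags.update({"sampler": "dramote", "audit": []})
        return _append_synthetic(data, empty), empty

    rounds = max(1, min(config.rounds, n_total))
    sizes = [n_total // rounds] * rounds
    for r in range(n_total % rounds):
        sizes[r] += 1

    def draw(size: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        pos = rng.choice(inner_min_idx.shape[0], size=size, p=importance.weights)
        a_inner = inner_min_idx[pos]
        b_inner = np.empty(size, dtype=int)
        for t in range(size):
            pool = safe_sets[pos[t]]
            b_inner[t] = pool[rng.integers(0, pool.shape[0])]
        u = rng.random(size)
        # map inner-row positions back to original-data row indices
        return inner_idx[a_inner], inner_idx[b_inner], u

    audit: list[dict] = []
    acc_a: list[np.ndarray] = []
    acc_b: list[np.ndarray] = []
    acc_u: list[np.ndarray] = []
    accepted_points: list[np.ndarray] = []

    if feedback_on:
        incumbent, _ = _score_batch(
            np.empty((0, data.n_features)), inner, val, config, clf_seed
        )

    for r, size in enumerate(sizes):
        best = None
        accepted = False
        for attempt in range(config.max_retries + 1):
            pa, pb, u = draw(size)
            pts = data.X[pa] + u[:, None] * (data.X[pb] - data.X[pa])
            if not feedback_on:
                audit.append(
                    {"round": r, "attempt": attempt, "score": None,
                     "accepted": True, "forced": False}
                )
                best = (pa, pb, u, pts, None)
                accepted = True
                break
            base = np.vstack(accepted_points) if accepted_points else np.empty(
                (0, data.n_features)
            )
            cand = np.vstack([base, pts]) if base.size else pts
            score, undefined = _score_batch(cand, inner, val, config, clf_seed)
            ok = score >= incumbent - config.acceptance_tolerance
            audit.append(
                {"round": r, "attempt": attempt, "score": score,
                 "accepted": bool(ok), "forced": False,
                 "metric_undefined": undefined}
            )
            if best is None or score > best[4]:
                best = (pa, pb, u, pts, score)
            if ok:
                best = (pa, pb, u, pts, score)
                incumbent = score
                accepted = True
                break
        if not accepted:
            # termination guarantee: keep the best-scoring batch seen
            pa, pb, u, pts, score = best
            audit.append(
                {"round": r, "attempt": config.max_retries + 1,
                 "score": score, "accepted": True, "forced": True}
            )
            if feedback_on and score is not None:
                incumbent = min(incumbent, score)
        else:
            pa, pb, u, pts, _ = best
        acc_a.append(pa)
        acc_b.append(pb)
        acc_u.append(u)
        accepted_points.append(pts)

    parent_a = np.concatenate(acc_a)
    parent_b = np.concatenate(acc_b)
    uu = np.concatenate(acc_u)
    batch = _interpolate(
        data,
        parent_a,
        parent_b,
        uu,
        flags={
            "sampler": "dramote",
            "audit": audit,
            "importance": importance,
            "safe_fallback": fallback,
            "feedback_on": feedback_on,
        },
    )
    return _append_synthetic(data, batch), batch
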
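"""Ensemble virtual screening.

Trains all six roster classifiers on one imbalance-corrected training set
(DRAMOTE by default), maps every member's output onto a commensurate
[0, 1] score, combines them (unweighted mean by default), and ranks
candidate compounds by the ensemble score to surface top-N predictions
for follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifiers import ROSTER, make_classifier, minority_score
from .data import LabeledDataset, Standardizer, apply_standardizer, fit_standardizer
from .errors import CapabilityError, FeatureCountMismatchError
from .feedback import FeedbackConfig, dramote_oversample
from .benchmark import apply_method
from .samplers import SamplerConfig

__all__ = [
    "EnsembleModel",
    "ScreeningResult",
    "train_ensemble",
    "score_candidates",
    "top_n",
    "featurize_smiles",
]


@dataclass(frozen=True)
class ScreeningResult:
    """One ranked candidate."""

    id: str
    score: float
    rank: int


@dataclass
class EnsembleModel:
    """Six fitted member classifiers with per-member score calibration.

    Margin members carry a min-max calibration over their training scores;
    probability members pass through.  All members were trained on the
    same corrected training matrix.
    """

    members: dict
    calibration: dict  # name -> (lo, hi) for margin members, None otherwise
    standardizer: Standardizer
    sampler_config: SamplerConfig
    combine: str = "mean"
    n_features: int = 0
    flags: dict = field(default_factory=dict)
    train_fingerprint: int = 0  # hash of the corrected training matrix


def _raw_member_score(clf, X: np.ndarray) -> np.ndarray:
    """Uncalibrated continuous score towards the +1 class."""
    classes = np.asarray(clf.classes_)
    if hasattr(clf, "predict_proba"):
        if classes.shape[0] == 1:
            return np.full(X.shape[0], 1.0 if classes[0] == 1 else 0.0)
        return clf.predict_proba(X)[:, int(np.flatnonzero(classes == 1)[0])]
    d = np.asarray(clf.decision_function(X), dtype=float)
    if classes.shape[0] == 2 and classes[1] != 1:
        d = -d
    return d


def train_ensemble(
    train: LabeledDataset,
    sampler_config: SamplerConfig | None = None,
    feedback_config: FeedbackConfig | None = None,
    classifiers: tuple[str, ...] = ROSTER,
    combine: str = "mean",
    seed: int = 0,
) -> EnsembleModel:
    """Correct the training set once, then fit all members on it.

    A member whose training fails is dropped with a flag as long as at
    least four members survive; fewer is an error.
    """
    train.require_both_classes()
    if combine not in ("mean", "median", "vote"):
        raise ValueError("combine must be mean|median|vote")
    sampler_config = sampler_config or SamplerConfig(method="dramote", seed=seed)
    std = fit_standardizer(train)
    train_z = LabeledDataset(apply_standardizer(std, train.X), train.y)
    corrected = apply_method(
        sampler_config.method, train_z, sampler_config, feedback_config
    )

    members: dict = {}
    calibration: dict = {}
    failures: dict = {}
    for name in classifiers:
        try:
            clf = make_classifier(name, seed=seed)
            clf.fit(corrected.X, corrected.y)
            raw = _raw_member_score(clf, corrected.X)
            if hasattr(clf, "predict_proba"):
                calibration[name] = None
            else:
                lo, hi = float(raw.min()), float(raw.max())
                calibration[name] = (lo, hi)
            members[name] = clf
        except Exception as exc:
            failures[name] = repr(exc)
    if len(members) < 4:
        raise RuntimeError(
            f"only {len(members)} members trained; failures: {failures}"
        )
    return EnsembleModel(
        members=members,
        calibration=calibration,
        standardizer=std,
        sampler_config=sampler_config,
        combine=combine,
        n_features=train.n_features,
        flags={"member_failures": failures} if failures else {},
        train_fingerprint=hash(corrected.X.tobytes()),
    )


def _calibrated_scores(model: EnsembleModel, Z: np.ndarray) -> np.ndarray:
    """(n_members, n_candidates) matrix of member scores in [0, 1]."""
    rows = []
    for name, clf in model.members.items():
        raw = _raw_member_score(clf, Z)
        cal = model.calibration[name]
        if cal is not None:
            lo, hi = cal
            if hi > lo:
                raw = np.clip((raw - lo) / (hi - lo), 0.0, 1.0)
            else:
                raw = np.full_like(raw, 0.5)
        rows.append(raw)
    return np.vstack(rows)


def score_candidates(model: EnsembleModel, candidates: np.ndarray) -> np.ndarray:
    """Ensemble score per candidate row, each in [0, 1]."""
    X = np.atleast_2d(np.asarray(candidates, dtype=float))
    if X.shape[1] != model.n_features:
        raise FeatureCountMismatchError(
            f"candidates have {X.shape[1]} features, model expects "
            f"{model.n_features}"
        )
    Z = apply_standardizer(model.standardizer, X)
    S = _calibrated_scores(model, Z)
    if model.combine == "mean":
        return S.mean(axis=0)
    if model.combine == "median":
        return np.median(S, axis=0)
    # vote: fraction of members predicting +1
    preds = np.vstack([clf.predict(Z) for clf in model.members.values()])
    return (preds == 1).mean(axis=0)


def top_n(scores, ids, n: int) -> list[ScreeningResult]:
    """The n highest-scoring candidates, score-descending; ties break by
    identifier ascending.  n beyond the candidate count truncates with a
    warning flag on the last entry's metadata-free contract (the list is
    simply shorter)."""
    scores = np.asarray(scores, dtype=float).ravel()
    ids = [str(i) for i in ids]
    if len(ids) != scores.shape[0]:
        raise ValueError("ids and scores differ in length")
    order = sorted(range(len(ids)), key=lambda i: (-scores[i], ids[i]))
    n_eff = min(n, len(ids))
    return [
        ScreeningResult(id=ids[i], score=float(scores[i]), rank=r + 1)
        for r, i in enumerate(order[:n_eff])
    ]


def featurize_smiles(
    smiles: list[str], radius: int = 2, n_bits: int = 1024
) -> tuple[np.ndarray, list[str], list[dict]]:
    """Optional chemistry hook: Morgan fingerprint bit vectors per SMILES.

    Requires RDKit at runtime; raises a capability error otherwise.
    Unparsable records are excluded and reported.  Returns
    (matrix, feature names, exclusion report).
    """
    try:
        from rdkit import Chem, RDLogger
        from rdkit.Chem import AllChem
    except ImportError as exc:  # pragma: no cover
        raise CapabilityError("RDKit is required for SMILES featurization") from exc
    RDLogger.DisableLog("rdApp.*")
    names = [f"morgan_r{radius}_bit{i}" for i in range(n_bits)]
    rows, report = [], []
    for rec_no, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            report.append({"record": rec_no, "smiles": smi, "reason": "unparsable"})
            continue
        fp = AllChem.GetMorganFingerprintAsBitVect(mol, radius, nBits=n_bits)
        rows.append(np.asarray(fp, dtype=float))
    X = np.vstack(rows) if rows else np.empty((0, n_bits))
    return X, names, report
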
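"""DRAMOTE: importance weighting, safe neighbours, feedback loop."""

import numpy as np
import pytest

from dramote import (
    FeedbackConfig,
    LabeledDataset,
    SamplerConfig,
    SyntheticBatch,
    dramote_oversample,
    feedback_accept,
    minority_importance,
    safe_neighbor_set,
    smote,
)
from dramote.errors import InsufficientMinorityError


class TestMinorityImportance:
    def test_risky_point_weighs_more(self, fixtures):
        ds = fixtures["one_hot_risk"]
        w = minority_importance(ds, FeedbackConfig(feedback_classifier="knn"))
        # row 0 sits inside the majority blob: highest misclassification risk
        assert w.weights[0] > max(w.weights[1:])
        assert w.weights.sum() == pytest.approx(1.0)

    def test_monotone_in_risk(self, fixtures):
        w = minority_importance(
            fixtures["one_hot_risk"], FeedbackConfig(feedback_classifier="knn")
        )
        order = np.argsort(w.risk)
        assert np.all(np.diff(w.weights[order]) >= -1e-12)

    def test_uniform_mode(self, imbalanced):
        w = minority_importance(
            imbalanced, FeedbackConfig(importance_mode="uniform")
        )
        m = imbalanced.n_minority
        np.testing.assert_allclose(w.weights, np.full(m, 1.0 / m))

    def test_equal_risks_uniform(self):
        # perfectly symmetric two-cluster layout: all minority rows carry
        # the same neighbourhood risk
        min_pts = np.array([[0.0, 0.0], [10.0, 10.0]])
        maj = np.array([[0.0, 1.0], [10.0, 11.0], [1.0, 0.0], [11.0, 10.0]])
        ds = LabeledDataset(np.vstack([min_pts, maj]), [1, 1, -1, -1, -1, -1])
        w = minority_importance(ds, FeedbackConfig(importance_mode="neighborhood"))
        np.testing.assert_allclose(w.weights, [0.5, 0.5])

    def test_cv_impossible_falls_back(self):
        ds = LabeledDataset(
            np.array([[0.0], [0.1], [5.0], [6.0], [7.0]]), [1, 1, -1, -1, -1]
        )
        w = minority_importance(
            ds, FeedbackConfig(feedback_classifier="knn", internal_folds=3)
        )
        # minority of 2 cannot support 3 stratified folds
        assert "fallback" in w.provenance or w.provenance.startswith("feedback")


class TestSafeNeighborSet:
    def _dataset(self):
        # minority: i=0 with neighbours 1 (safe, minority-surrounded) and
        # 2 (unsafe, buried among majority)
        min_pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.5]])
        extra_min = np.array([[1.2, 0.2], [0.8, -0.2], [1.0, 0.3]])
        maj = np.array(
            [[0.1, 1.6], [-0.1, 1.4], [0.0, 1.7], [0.2, 1.5], [-0.2, 1.6],
             [8.0, 8.0]]
        )
        X = np.vstack([min_pts, extra_min, maj])
        y = np.array([1] * 6 + [-1] * 6)
        return LabeledDataset(X, y)

    def test_unsafe_neighbor_excluded(self):
        ds = self._dataset()
        cfg = FeedbackConfig(safe_threshold=0.5, safe_k=5)
        partners, fallback = safe_neighbor_set(0, ds, cfg, k_neighbors=2)
        assert 2 not in partners.tolist()  # buried neighbour rejected
        assert 1 in partners.tolist()
        assert not fallback

    def test_all_unsafe_fallback_singleton(self):
        min_pts = np.array([[0.0, 0.0], [1.0, 0.0]])
        maj = np.vstack(
            [np.array([[1.0, 0.0]]) + 0.1 * d
             for d in np.array([[1, 0], [-1, 0], [0, 1], [0, -1], [1, 1]])]
        )
        ds = LabeledDataset(
            np.vstack([min_pts, maj]), [1, 1, -1, -1, -1, -1, -1]
        )
        partners, fallback = safe_neighbor_set(
            0, ds, FeedbackConfig(safe_threshold=0.0, safe_k=5), k_neighbors=1
        )
        assert fallback and partners.shape[0] == 1


class TestDramoteOversample:
    def test_count_matches_smote(self, imbalanced):
        cfg = SamplerConfig(seed=2)
        _, bs = smote(imbalanced, cfg)
        _, bd = dramote_oversample(
            imbalanced, cfg, FeedbackConfig(feedback_classifier="knn")
        )
        assert bd.n_points == bs.n_points

    def test_parent_reconstruction(self, imbalanced):
        _, b = dramote_oversample(
            imbalanced,
            SamplerConfig(method="dramote", seed=3),
            FeedbackConfig(feedback_classifier="knn"),
        )
        np.testing.assert_allclose(
            b.reconstruct(imbalanced.X), b.points, atol=1e-9
        )
        assert np.all(imbalanced.y[b.parent_a] == 1)
        assert np.all(imbalanced.y[b.parent_b] == 1)

    def test_byte_determinism(self, imbalanced):
        args = (
            imbalanced,
            SamplerConfig(method="dramote", seed=5),
            FeedbackConfig(feedback_classifier="knn"),
        )
        _, b1 = dramote_oversample(*args)
        _, b2 = dramote_oversample(*args)
        assert np.array_equal(b1.points, b2.points)
        assert np.array_equal(b1.u, b2.u)

    def test_dominant_parent_under_one_hot_risk(self, fixtures):
        # one minority point with out-of-fold score ~0, the rest ~1:
        # importance concentrates on it, so nearly all parents are row 0
        ds = fixtures["one_hot_risk"]
        fb = FeedbackConfig(feedback_classifier="knn", max_retries=0)
        fracs = []
        for seed in range(20):
            _, b = dramote_oversample(
                ds, SamplerConfig(method="dramote", seed=seed), fb
            )
            fracs.append(np.mean(b.parent_a == 0))
        assert np.mean(fracs) >= 0.9

    def test_insufficient_minority(self):
        ds = LabeledDataset(np.zeros((3, 1)), [1, -1, -1])
        with pytest.raises(InsufficientMinorityError):
            dramote_oversample(ds, SamplerConfig(method="dramote", seed=0))

    def test_loop_terminates_within_retry_budget(self, imbalanced):
        fb = FeedbackConfig(feedback_classifier="knn", max_retries=2, rounds=3)
        _, b = dramote_oversample(
            imbalanced, SamplerConfig(method="dramote", seed=1), fb
        )
        audit = b.flags["audit"]
        for r in range(3):
            entries = [e for e in audit if e["round"] == r]
            # at most R+1 evaluated batches (+1 bookkeeping entry if forced)
            assert len([e for e in entries if not e.get("forced")]) <= 3

    def test_metric_pluggability(self, imbalanced):
        fb = FeedbackConfig(feedback_classifier="knn", metric="f1")
        _, b = dramote_oversample(
            imbalanced, SamplerConfig(method="dramote", seed=1), fb
        )
        assert b.n_points > 0  # loop ran to completion under f1 control


class TestFeedbackAccept:
    def _splits(self, fixtures):
        ds = fixtures["separable"]
        rng = np.random.default_rng(0)
        idx = rng.permutation(ds.n_samples)
        return ds.subset(idx[30:]), ds.subset(idx[:30])

    def test_good_batch_accepted(self, fixtures):
        train, val = self._splits(fixtures)
        batch = SyntheticBatch.empty(train.n_features)
        cfg = FeedbackConfig(feedback_classifier="knn")
        accepted, score, flags = feedback_accept(batch, train, val, cfg, 0.5)
        assert accepted and score >= 0.5

    def test_impossible_incumbent_rejected(self, fixtures):
        train, val = self._splits(fixtures)
        batch = SyntheticBatch.empty(train.n_features)
        cfg = FeedbackConfig(feedback_classifier="knn")
        accepted, score, _ = feedback_accept(batch, train, val, cfg, 1.1)
        assert not accepted
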
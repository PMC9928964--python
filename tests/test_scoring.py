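"""Forest staging, vote proportions, kappa/confusion, confidence, LOSO."""

from __future__ import annotations

import numpy as np
import pytest

from earsleep.features import FeatureMatrix, N_FEATURES, feature_registry
from earsleep.io_core import Hypnogram, STAGES
from earsleep.scoring import (
    N_TREES,
    cohens_kappa,
    confidence,
    confusion,
    loso_cross_validate,
    predict_votes,
    train,
    votes_to_hypnogram,
)

COLS = [d.name for d in feature_registry()]


def _separable_dataset(n_per_stage=30, seed=0, spread=0.3):
    """84-d gaussian blobs, one center per stage: trivially separable."""
    rng = np.random.default_rng(seed)
    centers = rng.standard_normal((5, N_FEATURES)) * 3
    rows, labels = [], []
    for k, stage in enumerate(STAGES):
        rows.append(centers[k] + spread * rng.standard_normal((n_per_stage, N_FEATURES)))
        labels += [stage] * n_per_stage
    F = FeatureMatrix(np.vstack(rows), columns=COLS)
    return F, Hypnogram(labels=tuple(labels))


class TestTrainPredict:
    def test_separable_data_fits_cleanly(self):
        F, h = _separable_dataset()
        model = train([F], [h], seed=0)
        V = predict_votes(model, F)
        pred = votes_to_hypnogram(V, F.index)
        assert cohens_kappa(h, pred) > 0.95

    def test_same_seed_same_predictions(self):
        F, h = _separable_dataset()
        F2, _ = _separable_dataset(seed=99)
        a = predict_votes(train([F], [h], seed=5), F2)
        b = predict_votes(train([F], [h], seed=5), F2)
        np.testing.assert_array_equal(a, b)

    def test_wrong_dimension_rejected(self):
        F, h = _separable_dataset()
        bad = FeatureMatrix(np.asarray(F)[:, :50], columns=COLS[:50])
        with pytest.raises(ValueError, match="84"):
            train([bad], [h], seed=0)

    def test_absent_stage_warns_but_trains(self):
        F, h = _separable_dataset()
        keep = [i for i, s in enumerate(h.labels) if s != "REM"]
        F2 = FeatureMatrix(np.asarray(F)[keep], columns=COLS, index=keep)
        h2 = Hypnogram(labels=tuple(h.labels[i] for i in keep))
        with pytest.warns(UserWarning, match="REM"):
            model = train([F2], [h2], seed=0)
        assert predict_votes(model, F2).shape[1] == 5


class TestVotes:
    def test_rows_are_exact_tree_fractions(self):
        F, h = _separable_dataset(n_per_stage=10)
        V = predict_votes(train([F], [h], seed=1), F)
        np.testing.assert_allclose(V.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(
            np.round(V * N_TREES), V * N_TREES, atol=1e-9
        )

    def test_argmax_matches_per_tree_majority(self):
        """Winning class equals the majority over individual tree
        predictions, counted independently here."""
        F, h = _separable_dataset(n_per_stage=10, spread=3.0)  # noisy, mixed votes
        model = train([F], [h], seed=2)
        X = np.asarray(F)[:10]
        V = predict_votes(model, FeatureMatrix(X, columns=COLS))
        classes = model.forest.classes_
        per_tree = np.stack(
            [classes[t.predict(X).astype(int)] for t in model.forest.estimators_]
        )
        for i in range(10):
            counts = np.bincount(per_tree[:, i].astype(int), minlength=5)
            assert np.argmax(V[i]) == np.argmax(counts)

    def test_votes_to_hypnogram_argmax_and_ties(self):
        V = np.array(
            [
                [0.1, 0.1, 0.6, 0.1, 0.1],
                [0.3, 0.3, 0.2, 0.1, 0.1],  # W-N1 tie -> W by class order
            ]
        )
        h = votes_to_hypnogram(V, [0, 2], n_epochs=3)
        assert h.labels == ("N2", "UNSCORED", "W")


class TestKappa:
    def test_perfect_agreement(self):
        h = Hypnogram(labels=("W", "N1", "N2", "REM"))
        assert cohens_kappa(h, h) == 1.0

    def test_hand_worked_example(self):
        """p_o = 3/4, p_e = 1/2 -> kappa = 0.5."""
        a = Hypnogram(labels=("W", "W", "N2", "N2"))
        b = Hypnogram(labels=("W", "N2", "N2", "N2"))
        assert cohens_kappa(a, b) == pytest.approx(0.5)

    def test_cyclic_relabelling_gives_no_agreement(self):
        cycle = {"W": "N1", "N1": "N2", "N2": "N3", "N3": "REM", "REM": "W"}
        rng = np.random.default_rng(0)
        labels = tuple(rng.choice(STAGES, 60))
        a = Hypnogram(labels=labels)
        b = Hypnogram(labels=tuple(cycle[s] for s in labels))
        assert cohens_kappa(a, b) <= 0

    def test_symmetry_and_relabel_invariance(self, rng):
        perm = dict(zip(STAGES, ("N3", "REM", "W", "N2", "N1")))
        for _ in range(20):
            a = Hypnogram(labels=tuple(rng.choice(STAGES, 50)))
            b = Hypnogram(labels=tuple(rng.choice(STAGES, 50)))
            k = cohens_kappa(a, b)
            assert k == pytest.approx(cohens_kappa(b, a))
            ap = Hypnogram(labels=tuple(perm[s] for s in a.labels))
            bp = Hypnogram(labels=tuple(perm[s] for s in b.labels))
            assert k == pytest.approx(cohens_kappa(ap, bp))

    def test_matches_sklearn_reference(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for _ in range(10):
            a = Hypnogram(labels=tuple(rng.choice(STAGES, 80)))
            b = Hypnogram(labels=tuple(rng.choice(STAGES, 80)))
            assert cohens_kappa(a, b) == pytest.approx(
                cohen_kappa_score(a.labels, b.labels)
            )

    def test_unscored_dropped_pairwise(self):
        a = Hypnogram(labels=("W", "UNSCORED", "N2", "N2"))
        b = Hypnogram(labels=("W", "N2", "UNSCORED", "N2"))
        # only epochs 0 and 3 compared, both agree and marginals match
        assert cohens_kappa(a, b) == 1.0

    def test_degenerate_inputs(self):
        both_w = Hypnogram(labels=("W", "W"))
        assert cohens_kappa(both_w, both_w) == 1.0
        with pytest.raises(ValueError, match="no pairwise"):
            cohens_kappa(
                Hypnogram(labels=("UNSCORED",)), Hypnogram(labels=("W",))
            )
        with pytest.raises(ValueError, match="lengths"):
            cohens_kappa(Hypnogram(labels=("W",)), Hypnogram(labels=("W", "W")))


class TestConfusion:
    def test_identical_inputs_diagonal(self):
        h = Hypnogram(labels=("W", "N1", "N2", "N2", "N3", "REM"))
        M = confusion(h, h)
        assert M.sum() == 6
        assert np.all(M == np.diag(np.diag(M)))

    def test_hand_counts(self):
        a = Hypnogram(labels=("W", "W", "N2", "N2"))
        b = Hypnogram(labels=("W", "N2", "N2", "N2"))
        M = confusion(a, b)
        assert M[0, 0] == 1 and M[0, 2] == 1 and M[2, 2] == 2
        assert M.sum() == 4

    def test_marginals_reconstruct_stage_counts(self, rng):
        a = Hypnogram(labels=tuple(rng.choice(STAGES, 100)))
        b = Hypnogram(labels=tuple(rng.choice(STAGES, 100)))
        M = confusion(a, b)
        for k in range(5):
            assert M[k].sum() == sum(s == STAGES[k] for s in a.labels)
            assert M[:, k].sum() == sum(s == STAGES[k] for s in b.labels)


class TestConfidence:
    def test_one_hot_votes(self):
        assert confidence(np.eye(5)[[0, 2, 4]]) == 1.0

    def test_uniform_votes(self):
        assert confidence(np.full((4, 5), 0.2)) == pytest.approx(0.2)

    def test_mean_of_row_maxima(self):
        V = np.array([[0.6, 0.1, 0.1, 0.1, 0.1], [0.05, 0.05, 0.05, 0.05, 0.8]])
        assert confidence(V) == pytest.approx(0.7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confidence(np.zeros((0, 5)))


class TestLoso:
    def test_holdout_never_in_training_fold(self):
        data = []
        for s in ("s1", "s2", "s3"):
            F, h = _separable_dataset(n_per_stage=8, seed=hash(s) % 1000)
            data.append((s, F, h))
        results = loso_cross_validate(data, seed=0)
        assert len(results) == 3
        for r in results:
            assert r["subject"] not in r["train_subjects"]
            assert len(r["train_subjects"]) == 2

    def test_single_subject_rejected(self):
        F, h = _separable_dataset(n_per_stage=5)
        with pytest.raises(ValueError, match="2 subjects"):
            loso_cross_validate([("only", F, h)], seed=0)
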
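"""Random-forest sleep staging, agreement statistics, and vote confidence.

Epoch feature vectors are classified into the five stages by a random
forest of 100 trees.  The proportion of trees voting for a stage is an
estimate of that stage's likelihood: the winning proportion per epoch
is the classifier's confidence, and its mean over a recording predicts
scoring quality when no manual hypnogram exists.  Validation uses
leave-one-subject-out (LOSO) cross-validation with Cohen's kappa
against manual scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .features import N_FEATURES
from .io_core import Hypnogram, STAGES, STAGE_TO_INT, UNSCORED

N_TREES = 100


@dataclass
class StagingModel:
    """A trained 100-tree forest plus its fixed class order and seed."""

    forest: RandomForestClassifier
    seed: int

    @property
    def classes_present(self) -> np.ndarray:
        return self.forest.classes_


@dataclass
class ScoringResult:
    """Scored night: predicted hypnogram, agreement, and confidence."""

    hypnogram: Hypnogram
    votes: np.ndarray  # (n_accepted_epochs, 5)
    confidence: float
    kappa: float | None = None
    confusion: np.ndarray | None = None


def _stack_training(features_list, labels_list):
    xs, ys = [], []
    for F, h in zip(features_list, labels_list):
        y = np.array([h.labels[i] for i in F.index])
        keep = y != UNSCORED
        xs.append(np.asarray(F, dtype=float)[keep])
        ys.append(np.array([STAGE_TO_INT[s] for s in y[keep]]))
    X = np.vstack(xs)
    y = np.concatenate(ys)
    return X, y


def train(features_list, labels_list, seed: int = 0) -> StagingModel:
    """Fit the 100-tree forest on aligned (FeatureMatrix, Hypnogram) pairs.

    UNSCORED epochs are excluded from the training pairs.  A stage
    absent from all training data triggers a warning; the model still
    trains on the remaining classes.
    """
    if len(features_list) != len(labels_list):
        raise ValueError("features and labels lists differ in length")
    X, y = _stack_training(features_list, labels_list)
    if X.shape[1] != N_FEATURES:
        raise ValueError(f"expected {N_FEATURES} features, got {X.shape[1]}")
    present = set(y)
    absent = [s for s, i in STAGE_TO_INT.items() if i not in present]
    if absent:
        warnings.warn(f"stage(s) absent from training data: {absent}", stacklevel=2)
    forest = RandomForestClassifier(
        n_estimators=N_TREES,
        max_features="sqrt",
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return StagingModel(forest=forest, seed=seed)


def predict_votes(m: StagingModel, F) -> np.ndarray:
    """Per-epoch class-vote proportions (n_epochs, 5), rows summing to 1.

    Votes are hard per-tree predictions, so every proportion is an
    exact multiple of 1/100.
    """
    X = np.asarray(F, dtype=float)
    if X.shape[1] != N_FEATURES:
        raise ValueError(f"expected {N_FEATURES} features, got {X.shape[1]}")
    counts = np.zeros((X.shape[0], len(STAGES)), dtype=int)
    classes = m.forest.classes_
    for tree in m.forest.estimators_:
        pred = classes[tree.predict(X).astype(int)]
        for k in range(len(STAGES)):
            counts[:, k] += pred == k
    return counts / float(N_TREES)


def votes_to_hypnogram(V: np.ndarray, epoch_index, n_epochs: int | None = None) -> Hypnogram:
    """Argmax votes -> stage labels; epochs without votes become UNSCORED.

    ``epoch_index`` gives the epoch number of each vote row; ties go to
    the earlier class in the fixed order W < N1 < N2 < N3 < REM.
    """
    epoch_index = list(epoch_index)
    if n_epochs is None:
        n_epochs = (max(epoch_index) + 1) if epoch_index else 0
    labels = [UNSCORED] * n_epochs
    winners = np.argmax(V, axis=1) if len(V) else []
    for row, i in enumerate(epoch_index):
        labels[i] = STAGES[winners[row]]
    return Hypnogram(labels=tuple(labels))


def confidence(V: np.ndarray) -> float:
    """Mean over epochs of the winning vote proportion; in [0.2, 1]."""
    V = np.asarray(V, dtype=float)
    if V.size == 0:
        raise ValueError("empty vote matrix")
    return float(V.max(axis=1).mean())


def _paired_codes(a: Hypnogram, b: Hypnogram) -> tuple[np.ndarray, np.ndarray]:
    if len(a) != len(b):
        raise ValueError(f"hypnogram lengths differ: {len(a)} vs {len(b)}")
    ai, bi = a.to_int(), b.to_int()
    keep = (ai >= 0) & (bi >= 0)
    return ai[keep], bi[keep]


def cohens_kappa(a: Hypnogram, b: Hypnogram) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    Epochs UNSCORED in either input are dropped pairwise.  When both
    inputs are the same constant (p_e = 1), kappa is defined as 1.
    """
    ai, bi = _paired_codes(a, b)
    if len(ai) == 0:
        raise ValueError("no pairwise-scored epochs to compare")
    n = len(ai)
    po = float(np.mean(ai == bi))
    pe = 0.0
    for k in range(len(STAGES)):
        pe += np.mean(ai == k) * np.mean(bi == k)
    if pe >= 1.0 - 1e-12:
        return 1.0 if po == 1.0 else 0.0
    return float((po - pe) / (1.0 - pe))


def confusion(a: Hypnogram, b: Hypnogram) -> np.ndarray:
    """5x5 counts, rows = first (manual) input, columns = second (automatic)."""
    ai, bi = _paired_codes(a, b)
    M = np.zeros((5, 5), dtype=int)
    for x, y in zip(ai, bi):
        M[x, y] += 1
    return M


def loso_cross_validate(dataset, seed: int = 0, graded=None):
    """Leave-one-subject-out validation over a labeled dataset.

    ``dataset`` is a list of records ``(subject_id, FeatureMatrix,
    Hypnogram)`` (normalized features).  For each subject a model is
    trained on every other subject's recordings — pooling whatever
    datasets are in ``dataset`` — and applied to that subject's
    recordings.  Returns a list of dicts with per-recording kappa,
    confidence, predicted hypnogram, and the training-fold subjects.
    """
    subjects = sorted({s for s, _, _ in dataset})
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    results = []
    for holdout in subjects:
        train_recs = [(F, h) for s, F, h in dataset if s != holdout]
        model = train([F for F, _ in train_recs], [h for _, h in train_recs], seed=seed)
        for idx, (s, F, h) in enumerate(dataset):
            if s != holdout:
                continue
            V = predict_votes(model, F)
            pred = votes_to_hypnogram(V, F.index, n_epochs=len(h))
            results.append(
                {
                    "dataset_index": idx,
                    "subject": s,
                    "kappa": cohens_kappa(h, pred),
                    "confidence": confidence(V),
                    "predicted": pred,
                    "votes": V,
                    "train_subjects": sorted({t for t, _, _ in dataset if t != holdout}),
                }
            )
    results.sort(key=lambda r: r["dataset_index"])
    return results
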
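"""Tournament leave-pair-out (TLPO) cross-validated AUC estimation.

Every possible pair of participants is held out in turn; a logistic
regression is trained on the story vectors of all remaining participants
(each story inherits its participant's label) and scores the two held-out
participants by averaging their per-story predicted probabilities.  Each
held-out comparison is a tournament match; participants are ranked by win
count (ties broken by mean cross-validated score, then by id) and the AUC is
the fraction of opposite-label pairs the final ranking orders correctly,
with ties counted 1/2.

The hold-out unit is the participant: all of a participant's stories leave
the training fold together, so no recall of a held-out subject can leak into
training.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

__all__ = [
    "LabeledDataset",
    "ClassifierSpec",
    "TLPOResult",
    "fit_fold",
    "participant_score",
    "tournament_ranking",
    "tlpo_auc",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """Fixed logistic-regression configuration used in every fold.

    Features are standardized by training-fold mean/SD; the model is
    L2-regularized with unit inverse strength and a deterministic solver.
    """

    C: float = 1.0
    tol: float = 1e-8
    max_iter: int = 2000
    standardize: bool = True


@dataclass
class LabeledDataset:
    """Story vectors grouped by participant with one binary label each."""

    participant_ids: list[str]
    features: dict[str, np.ndarray]  # pid -> (n_stories, n_features)
    labels: dict[str, int]  # pid -> 0/1

    def __post_init__(self) -> None:
        for pid in self.participant_ids:
            X = np.atleast_2d(np.asarray(self.features[pid], dtype=float))
            if X.shape[0] < 1:
                raise ValueError(f"participant {pid} has no story vectors")
            self.features[pid] = X
            if self.labels[pid] not in (0, 1):
                raise ValueError(f"participant {pid}: label must be 0/1")

    @classmethod
    def from_story_frame(cls, story_df, labels: Mapping[str, int]) -> "LabeledDataset":
        """Build from a long table with ``participant_id`` and feature columns."""
        feature_cols = [
            c for c in story_df.columns if c not in ("participant_id", "story_id")
        ]
        features = {}
        ids = []
        for pid, grp in story_df.groupby("participant_id", sort=True):
            if pid not in labels:
                continue
            ids.append(str(pid))
            features[str(pid)] = grp[feature_cols].to_numpy(dtype=float)
        return cls(
            participant_ids=ids,
            features=features,
            labels={pid: int(labels[pid]) for pid in ids},
        )

    def class_counts(self) -> tuple[int, int]:
        values = [self.labels[p] for p in self.participant_ids]
        return values.count(1), values.count(0)


@dataclass(frozen=True)
class TLPOResult:
    participant_ids: tuple[str, ...]
    labels: tuple[int, ...]
    scores: tuple[float, ...]  # mean cross-validated score per participant
    win_counts: tuple[float, ...]
    ranking: tuple[str, ...]  # best (most case-like) first
    auc: float
    n_folds: int
    mode: str


def fit_fold(
    X: np.ndarray, y: np.ndarray, spec: ClassifierSpec | None = None
) -> Callable[[np.ndarray], np.ndarray]:
    """Train one fold's logistic regression; returns a probability scorer.

    Training rows are story vectors labelled with their participant's label.
    Raises on a single-class fold (the model would be undefined).
    """
    spec = spec or ClassifierSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training fold contains a single class")
    if spec.standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
    else:
        mu = np.zeros(X.shape[1])
        sd = np.ones(X.shape[1])
    # default penalty is ridge (L2); C is the inverse regularization strength
    model = LogisticRegression(
        C=spec.C,
        tol=spec.tol,
        max_iter=spec.max_iter,
        solver="lbfgs",
    )
    model.fit((X - mu) / sd, y)

    def scorer(vectors: np.ndarray) -> np.ndarray:
        V = np.atleast_2d(np.asarray(vectors, dtype=float))
        return model.predict_proba((V - mu) / sd)[:, 1]

    return scorer


def participant_score(
    scorer: Callable[[np.ndarray], np.ndarray], vectors: np.ndarray
) -> float:
    """Participant-level prediction: simple average of per-story scores."""
    V = np.atleast_2d(np.asarray(vectors, dtype=float))
    if V.shape[0] < 1:
        raise ValueError("participant has no vectors to score")
    return float(np.mean(scorer(V)))


def tournament_ranking(
    win_counts: Mapping[str, float], mean_scores: Mapping[str, float]
) -> list[str]:
    """Rank participants by win count, then mean score, then id (descending)."""
    return sorted(
        win_counts,
        key=lambda pid: (-win_counts[pid], -mean_scores[pid], pid),
    )


def _ranking_auc(
    ids: Sequence[str],
    labels: Mapping[str, int],
    win_counts: Mapping[str, float],
    mean_scores: Mapping[str, float],
) -> float:
    """Fraction of opposite-label pairs ordered correctly; ties count 1/2."""
    pos = [p for p in ids if labels[p] == 1]
    neg = [p for p in ids if labels[p] == 0]
    total = 0.0
    for p in pos:
        kp = (win_counts[p], mean_scores[p])
        for q in neg:
            kq = (win_counts[q], mean_scores[q])
            if kp > kq:
                total += 1.0
            elif kp == kq:
                total += 0.5
    return total / (len(pos) * len(neg))


def tlpo_auc(
    data: LabeledDataset,
    spec: ClassifierSpec | None = None,
    mode: str = "all_pairs",
    fold_callback: Callable[[tuple[str, str], set[str]], None] | None = None,
) -> TLPOResult:
    """Tournament leave-pair-out cross-validation over participants.

    ``mode='all_pairs'`` holds out every unordered pair of participants and
    estimates the AUC from the final tournament ranking.  With
    ``mode='cross_label_pairs'`` only opposite-label pairs are held out and
    the AUC is the classical leave-pair-out estimate — the fraction of
    held-out cross-label pairs each fold orders correctly (ranking by win
    count would be biased there, since the two classes play different
    opponents).  ``fold_callback(pair, train_ids)`` is invoked per fold,
    mainly to let callers audit fold composition.
    """
    if mode not in ("all_pairs", "cross_label_pairs"):
        raise ValueError(f"unknown mode {mode!r}")
    spec = spec or ClassifierSpec()
    ids = list(data.participant_ids)
    n_pos, n_neg = data.class_counts()
    if n_pos < 2 or n_neg < 2:
        raise ValueError("need at least 2 participants per class")

    pairs = [
        (a, b)
        for a, b in combinations(ids, 2)
        if mode == "all_pairs" or data.labels[a] != data.labels[b]
    ]

    win_counts = {pid: 0.0 for pid in ids}
    score_sums = {pid: 0.0 for pid in ids}
    score_counts = {pid: 0 for pid in ids}
    cross_correct = 0.0
    n_cross = 0

    n_skipped = 0
    for a, b in pairs:
        train_ids = [p for p in ids if p not in (a, b)]
        # Holding out both members of a 2-participant class would leave a
        # single-class training fold; such pairs cannot be scored.
        if len({data.labels[p] for p in train_ids}) < 2:
            n_skipped += 1
            continue
        X = np.vstack([data.features[p] for p in train_ids])
        y = np.concatenate(
            [np.full(data.features[p].shape[0], data.labels[p]) for p in train_ids]
        )
        if fold_callback is not None:
            fold_callback((a, b), set(train_ids))
        scorer = fit_fold(X, y, spec)
        s_a = participant_score(scorer, data.features[a])
        s_b = participant_score(scorer, data.features[b])
        if s_a > s_b:
            win_counts[a] += 1.0
        elif s_b > s_a:
            win_counts[b] += 1.0
        else:
            win_counts[a] += 0.5
            win_counts[b] += 0.5
        if data.labels[a] != data.labels[b]:
            n_cross += 1
            hi, lo = (s_a, s_b) if data.labels[a] == 1 else (s_b, s_a)
            cross_correct += 1.0 if hi > lo else (0.5 if hi == lo else 0.0)
        for pid, s in ((a, s_a), (b, s_b)):
            score_sums[pid] += s
            score_counts[pid] += 1

    mean_scores = {
        pid: (score_sums[pid] / score_counts[pid]) if score_counts[pid] else 0.0
        for pid in ids
    }
    ranking = tournament_ranking(win_counts, mean_scores)
    if mode == "all_pairs":
        auc = _ranking_auc(ids, data.labels, win_counts, mean_scores)
    else:
        auc = cross_correct / n_cross
    return TLPOResult(
        participant_ids=tuple(ids),
        labels=tuple(data.labels[p] for p in ids),
        scores=tuple(mean_scores[p] for p in ids),
        win_counts=tuple(win_counts[p] for p in ids),
        ranking=tuple(ranking),
        auc=float(auc),
        n_folds=len(pairs) - n_skipped,
        mode=mode,
    )
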
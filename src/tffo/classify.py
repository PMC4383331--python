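"""K-nearest-neighbor discrimination with leave-one-out cross-validation.

The classifier operates on per-subject Stockwell feature vectors with the
Euclidean metric.  Each subject is predicted by the majority label of its K
nearest training vectors; when K is even and the vote ties, the single
closest neighbor casts the deciding vote.  Cross-validation is subject-wise
leave-one-out: *all* vectors recorded from the held-out subject are withheld
from the training set, so a subject can never vote for itself.

The accompanying distance score for a vector is the sum of Euclidean
distances to its k nearest peers — small for vectors embedded deep inside a
class cluster, large for outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = ["ClassifierConfig", "CVResult", "knn_distance_score", "loo_cv", "significance"]

PATIENT, HEALTHY = "patient", "healthy"


class ConfigurationError(ValueError):
    pass


@dataclass
class ClassifierConfig:
    """KNN configuration: Euclidean metric, closest-neighbor tie break.

    K must satisfy 1 ≤ K ≤ ⌊n_training_vectors / 2⌋.
    """

    k: int

    def validate(self, n_vectors: int) -> None:
        if not 1 <= self.k <= n_vectors // 2:
            raise ConfigurationError(
                f"K={self.k} outside 1..floor({n_vectors}/2)={n_vectors // 2}"
            )


@dataclass
class CVResult:
    """Leave-one-out metrics; healthy is the negative class.

    ``margin`` is the mean normalized neighbor margin over held-out
    subjects, (d_opposite − d_own) / (d_opposite + d_own) with d_own /
    d_opposite the distance to the nearest training vector of the subject's
    own / the other class: a continuous separation measure in [−1, 1] that
    stays informative when accuracy saturates at 1.
    """

    predictions: pd.Series
    labels: pd.Series
    distance_scores: pd.Series
    accuracy: float
    specificity: float
    sensitivity: float
    n_subjects: int
    margin: float = float("nan")
    params: dict = field(default_factory=dict)


def knn_distance_score(x, others, k: int) -> float:
    """Sum of Euclidean distances from ``x`` to its ``k`` nearest rows of ``others``."""
    others = np.atleast_2d(np.asarray(others, dtype=float))
    if others.shape[0] == 0:
        raise ConfigurationError("others is empty")
    if k > others.shape[0]:
        raise ConfigurationError(f"k={k} exceeds {others.shape[0]} candidate vectors")
    d = np.linalg.norm(others - np.asarray(x, dtype=float)[None, :], axis=1)
    return float(np.sort(d)[:k].sum())


def _vote(dist_row: np.ndarray, train_labels: np.ndarray, k: int) -> str:
    """Majority vote of the k nearest vectors; ties go to the closest neighbor.

    Distance ties are broken by stable input order (vectors are pre-sorted by
    subject id), making the vote deterministic.
    """
    order = np.argsort(dist_row, kind="stable")[:k]
    votes = train_labels[order]
    n_pat = int(np.sum(votes == PATIENT))
    n_heal = k - n_pat
    if n_pat > n_heal:
        return PATIENT
    if n_heal > n_pat:
        return HEALTHY
    return str(votes[0])  # even K, tied vote: closest neighbor decides


def _loo_predict(dist, row_subjects, subjects, label_of, k: int, score_k: int):
    """Core LOO loop over a precomputed vector-distance matrix."""
    preds, scores, margins = {}, {}, {}
    subj_rows = {s: np.flatnonzero(row_subjects == s) for s in subjects}
    for subj in subjects:
        test_rows = subj_rows[subj]
        train_rows = np.flatnonzero(row_subjects != subj)
        ClassifierConfig(k).validate(len(train_rows))
        train_labels = np.array([label_of[s] for s in row_subjects[train_rows]])
        own_mask = train_labels == label_of[subj]
        row_votes, row_min, row_scores, row_margin = [], [], [], []
        for r in test_rows:
            d = dist[r, train_rows]
            row_votes.append(_vote(d, train_labels, k))
            row_min.append(d.min())
            row_scores.append(np.sort(d)[:score_k].sum())
            d_own, d_opp = d[own_mask].min(), d[~own_mask].min()
            denom = d_own + d_opp
            row_margin.append((d_opp - d_own) / denom if denom > 0 else 0.0)
        if len(row_votes) == 1:
            preds[subj] = row_votes[0]
        else:
            n_pat = sum(v == PATIENT for v in row_votes)
            n_heal = len(row_votes) - n_pat
            if n_pat != n_heal:
                preds[subj] = PATIENT if n_pat > n_heal else HEALTHY
            else:  # tied across the subject's vectors: closest vector decides
                preds[subj] = row_votes[int(np.argmin(row_min))]
        scores[subj] = float(np.mean(row_scores))
        margins[subj] = float(np.mean(row_margin))
    return preds, scores, margins


def _metrics(preds: dict, label_of: dict, subjects) -> tuple[float, float, float]:
    correct = np.array([preds[s] == label_of[s] for s in subjects])
    is_pat = np.array([label_of[s] == PATIENT for s in subjects])
    accuracy = float(correct.mean())
    sensitivity = float(correct[is_pat].mean()) if is_pat.any() else float("nan")
    specificity = float(correct[~is_pat].mean()) if (~is_pat).any() else float("nan")
    return accuracy, specificity, sensitivity


def _prepare(features):
    values = np.asarray(features.values, dtype=float)
    row_subjects = np.asarray(features.values.index)
    labels = pd.Series(features.labels)
    order = np.argsort(row_subjects, kind="stable")
    return values[order], row_subjects[order], labels


def loo_cv(features, k: int, score_k: int | None = None) -> CVResult:
    """Subject-wise leave-one-out KNN cross-validation.

    Parameters
    ----------
    features : FeatureMatrix (or any object with a ``values`` DataFrame and a
        ``labels`` Series indexed by subject).  Multiple rows per subject are
        supported: every vector of the held-out subject is voted on and the
        subject's prediction is the majority over its vectors (the closest
        vector decides ties); training vectors carry their subject's label.
    k : int
        Number of voting neighbors, 1 ≤ K ≤ ⌊n_train/2⌋.
    score_k : int, optional
        Neighbor count for the per-subject distance score (defaults to ``k``).
    """
    values, row_subjects, labels = _prepare(features)
    subjects = sorted(labels.index)
    counts = labels.value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ConfigurationError("need at least 2 subjects per class for LOO")
    dist = cdist(values, values)
    label_of = labels.to_dict()
    preds, scores, margins = _loo_predict(
        dist, row_subjects, subjects, label_of, k, k if score_k is None else score_k
    )
    accuracy, specificity, sensitivity = _metrics(preds, label_of, subjects)
    return CVResult(
        predictions=pd.Series({s: preds[s] for s in subjects}),
        labels=labels.loc[subjects],
        distance_scores=pd.Series({s: scores[s] for s in subjects}),
        accuracy=accuracy,
        specificity=specificity,
        sensitivity=sensitivity,
        n_subjects=len(subjects),
        margin=float(np.mean([margins[s] for s in subjects])),
        params={"k": k},
    )


def significance(
    features, k: int, n_perm: int = 199, seed: int = 0, method: str = "permutation"
) -> float:
    """p-value for the LOO accuracy.

    ``method="permutation"`` (default): subject labels are permuted
    ``n_perm`` times and p is the plus-one-corrected fraction of
    permutations whose LOO accuracy reaches the observed one; the distance
    matrix is computed once and shared across permutations.
    ``method="binomial"``: exact binomial tail P(X ≥ n_correct) with
    X ~ Binomial(n_subjects, 1/2) — cheaper, but it ignores the dependence
    between folds and the sub-1/2 LOO chance level, so the permutation
    test is the preferred convention.
    """
    if method == "binomial":
        from scipy.stats import binomtest

        cv = loo_cv(features, k)
        n_correct = int(round(cv.accuracy * cv.n_subjects))
        return float(binomtest(n_correct, cv.n_subjects, 0.5, alternative="greater").pvalue)
    if method != "permutation":
        raise ConfigurationError(f"unknown significance method {method!r}")
    if n_perm < 100:
        raise ConfigurationError("n_perm must be >= 100")
    values, row_subjects, labels = _prepare(features)
    subjects = sorted(labels.index)
    dist = cdist(values, values)
    label_of = labels.to_dict()
    preds, _, _ = _loo_predict(dist, row_subjects, subjects, label_of, k, k)
    observed = _metrics(preds, label_of, subjects)[0]
    rng = np.random.default_rng(seed)
    base = labels.loc[subjects].to_numpy()
    hits = 0
    for _ in range(n_perm):
        perm = base.copy()
        rng.shuffle(perm)
        perm_label_of = dict(zip(subjects, perm))
        p, _, _ = _loo_predict(dist, row_subjects, subjects, perm_label_of, k, k)
        if _metrics(p, perm_label_of, subjects)[0] >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)
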
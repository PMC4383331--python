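"""KNN-LOO classifier against hand-worked examples and a naive oracle."""

import numpy as np
import pandas as pd
import pytest

from tffo import knn_distance_score, loo_cv, significance
from tffo.classify import ConfigurationError
from tffo.timefreq import FeatureMatrix


def features_from(values: dict, labels: dict) -> FeatureMatrix:
    subjects = list(values)
    return FeatureMatrix(
        values=pd.DataFrame(
            np.atleast_2d([np.atleast_1d(values[s]) for s in subjects]), index=subjects
        ),
        labels=pd.Series(labels),
        provenance={},
    )


def naive_loo_knn(values: dict, labels: dict, k: int) -> dict:
    """Independent re-implementation: exhaustive distances, explicit vote.

    For each subject: rank every other subject by Euclidean distance (ties
    by subject-id order), majority label of the top k; an even-K tie goes to
    the single nearest neighbor.
    """
    preds = {}
    for s in sorted(values):
        others = sorted(t for t in values if t != s)
        dists = [(float(np.linalg.norm(np.atleast_1d(values[s]) - np.atleast_1d(values[t]))), i, t)
                 for i, t in enumerate(others)]
        dists.sort()
        top = [labels[t] for _, _, t in dists[:k]]
        n_pat = top.count("patient")
        if n_pat > k - n_pat:
            preds[s] = "patient"
        elif n_pat < k - n_pat:
            preds[s] = "healthy"
        else:
            preds[s] = top[0]
    return preds


class TestDistanceScore:
    def test_duplicate_vector_scores_zero(self):
        assert knn_distance_score([1.0, 2.0], [[1.0, 2.0], [5.0, 5.0]], k=1) == 0.0

    def test_hand_enumerated_sum(self):
        # distances from 0 to {3, 4}: nearest two sum to 7
        assert knn_distance_score([0.0], [[3.0], [4.0]], k=2) == 7.0

    def test_k_equal_to_pool_is_total_distance(self, rng):
        x = rng.normal(size=4)
        others = rng.normal(size=(6, 4))
        total = sum(float(np.linalg.norm(x - o)) for o in others)
        assert knn_distance_score(x, others, k=6) == pytest.approx(total)

    def test_k_too_large_rejected(self):
        with pytest.raises(ConfigurationError):
            knn_distance_score([0.0], [[1.0]], k=2)


class TestLooCv:
    def test_separated_classes_classify_perfectly(self, rng):
        values = {f"h{i}": rng.normal(0, 0.1, 3) for i in range(5)}
        values |= {f"p{i}": rng.normal(10, 0.1, 3) for i in range(5)}
        labels = {s: ("healthy" if s.startswith("h") else "patient") for s in values}
        cv = loo_cv(features_from(values, labels), k=3)
        assert (cv.accuracy, cv.specificity, cv.sensitivity) == (1.0, 1.0, 1.0)

    def test_even_k_tie_goes_to_closest_neighbor(self):
        """Hand-worked vote: K=2 neighbors disagree → nearest one decides."""
        values = {"a": 0.0, "b": 1.0, "c": 0.35, "d": 5.0, "e": 10.0, "f": 10.5}
        labels = {"a": "healthy", "b": "healthy", "c": "patient",
                  "d": "patient", "e": "healthy", "f": "patient"}
        cv = loo_cv(features_from(values, labels), k=2)
        # for subject a the two nearest are c (0.35, patient) and b (1.0, healthy):
        # tied vote, closest neighbor c casts the deciding vote
        assert cv.predictions["a"] == "patient"

    @pytest.mark.parametrize("trial", range(6))
    def test_matches_naive_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(4, 11))
        values = {f"s{i:02d}": rng.normal(0, 1, 3) for i in range(n)}
        labels = {s: ("healthy" if i < n // 2 else "patient")
                  for i, s in enumerate(sorted(values))}
        k = int(rng.integers(1, (n - 1) // 2 + 1))
        cv = loo_cv(features_from(values, labels), k=k)
        assert cv.predictions.to_dict() == naive_loo_knn(values, labels, k)

    def test_metrics_identity(self, rng):
        values = {f"s{i}": rng.normal(0, 1, 2) for i in range(10)}
        labels = {s: ("healthy" if i % 2 else "patient")
                  for i, s in enumerate(sorted(values))}
        cv = loo_cv(features_from(values, labels), k=3)
        correct = (cv.predictions == cv.labels)
        tp = int((correct & (cv.labels == "patient")).sum())
        tn = int((correct & (cv.labels == "healthy")).sum())
        assert cv.accuracy == (tp + tn) / cv.n_subjects

    def test_singleton_class_rejected(self):
        values = {"a": 0.0, "b": 1.0, "c": 2.0}
        labels = {"a": "healthy", "b": "healthy", "c": "patient"}
        with pytest.raises(ConfigurationError):
            loo_cv(features_from(values, labels), k=1)

    def test_no_leakage_of_held_out_subject(self, rng):
        """The held-out subject's own vectors never enter its training set."""
        values = {f"s{i}": rng.normal(0, 1, 3) for i in range(8)}
        labels = {s: ("healthy" if i < 4 else "patient")
                  for i, s in enumerate(sorted(values))}
        perturbed = dict(values)
        perturbed["s0"] = values["s0"] + rng.normal(0, 5, 3)
        cv = loo_cv(features_from(perturbed, labels), k=3)
        # direct prediction of perturbed s0 from the *original* other subjects
        others = {s: v for s, v in values.items() if s != "s0"}
        direct = naive_loo_knn({**others, "s0": perturbed["s0"]}, labels, 3)["s0"]
        assert cv.predictions["s0"] == direct

    def test_shuffled_labels_give_chance_accuracy(self, rng):
        """Permuting labels of separable data drives accuracy to LOO chance.

        Oracle: under a random label permutation 1-NN correctness is the
        probability that a fixed other subject carries the same permuted
        label, (n_c − 1)/(n − 1) = 5/11 for 6 + 6 subjects (the leave-one-out
        chance level, slightly below 1/2).
        """
        values = {f"h{i}": rng.normal(0, 0.1, 2) for i in range(6)}
        values |= {f"p{i}": rng.normal(8, 0.1, 2) for i in range(6)}
        base = ["healthy"] * 6 + ["patient"] * 6
        accs = []
        for _ in range(200):
            perm = list(rng.permutation(base))
            labels = dict(zip(sorted(values), perm))
            accs.append(loo_cv(features_from(values, labels), k=1).accuracy)
        se = np.std(accs) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 5 / 11) < 3 * max(se, 0.01)


class TestSignificance:
    def separable(self, rng, n_h=5, n_p=5):
        values = {f"h{i}": rng.normal(0, 0.1, 2) for i in range(n_h)}
        values |= {f"p{i}": rng.normal(8, 0.1, 2) for i in range(n_p)}
        labels = {s: ("healthy" if s.startswith("h") else "patient") for s in values}
        return features_from(values, labels)

    def test_separable_data_beats_every_permutation(self, rng):
        """p attains the plus-one floor 1/(n_perm + 1).

        Unequal class sizes (8 vs 7) keep the label complement out of the
        permutation space, so only a draw reproducing the exact labelling
        (probability 1/C(15,7) per draw) could tie the observed accuracy.
        """
        p = significance(self.separable(rng, 8, 7), k=1, n_perm=199, seed=0)
        assert p == pytest.approx(1 / 200)

    def test_deterministic_under_fixed_seed(self, rng):
        fm = self.separable(rng)
        assert significance(fm, 1, n_perm=149, seed=5) == significance(fm, 1, n_perm=149, seed=5)

    def test_null_pvalues_uniform(self):
        """Pure-noise features: p-values not distinguishable from U(0,1)."""
        from scipy.stats import kstest

        ps = []
        for ds in range(30):
            rng = np.random.default_rng(900 + ds)
            values = {f"s{i}": rng.normal(0, 1, 3) for i in range(8)}
            labels = {s: ("healthy" if i < 4 else "patient")
                      for i, s in enumerate(sorted(values))}
            ps.append(significance(features_from(values, labels), 1, n_perm=119, seed=ds))
        assert kstest(ps, "uniform").pvalue > 0.01
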
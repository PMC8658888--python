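import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crnnqsar.data_io import LatentMatrix
from crnnqsar.errors import MetricUndefinedError
from crnnqsar.evaluation import (cluster_split, kfold, r_squared, roc_auc)


def brute_force_auc(labels, scores):
    """Exhaustive pair counting: P(s+ > s-) + 0.5 P(tie)."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_worked_example(self):
        assert roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_is_half(self):
        assert roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_single_class_undefined(self):
        with pytest.raises(MetricUndefinedError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 4)),
                    min_size=2, max_size=12))
    def test_matches_brute_force_pair_counting(self, pairs):
        labels = [p[0] for p in pairs]
        scores = [p[1] / 4 for p in pairs]  # coarse grid forces ties
        if len(set(labels)) < 2:
            return
        assert roc_auc(labels, scores) == \
            pytest.approx(brute_force_auc(labels, scores), abs=1e-12)


class TestRSquared:
    def test_perfect_fit(self):
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_mean_prediction_scores_zero(self):
        y = [0.0, 1.0, 2.0]
        assert r_squared(y, [1.0, 1.0, 1.0]) == pytest.approx(0.0)

    def test_worked_example(self):
        assert r_squared([0, 1, 2], [0, 1, 1]) == pytest.approx(0.5)

    def test_zero_variance_undefined(self):
        with pytest.raises(MetricUndefinedError):
            r_squared([1.0, 1.0], [0.5, 1.5])

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.standard_normal(10)
        yhat = rng.standard_normal(10)
        expected = 1 - ((y - yhat) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert r_squared(y, yhat) == pytest.approx(expected, abs=1e-12)


class TestKFold:
    def test_balanced_disjoint_exhaustive(self):
        split = kfold(10, k=5, seed=0)
        sizes = [len(f) for f in split.test_folds]
        assert sizes == [2] * 5
        all_idx = np.concatenate(split.test_folds)
        assert sorted(all_idx) == list(range(10))

    def test_deterministic(self):
        a = kfold(20, k=5, seed=9)
        b = kfold(20, k=5, seed=9)
        for fa, fb in zip(a.test_folds, b.test_folds):
            np.testing.assert_array_equal(fa, fb)

    def test_isomer_pairs_share_folds(self):
        # 35 pairs as 35 groups: both members of a pair land in one fold
        groups = np.repeat(np.arange(35), 2)
        split = kfold(70, k=5, seed=1, groups=groups)
        for fold in split.test_folds:
            fold_groups = groups[fold]
            for g in set(fold_groups.tolist()):
                assert (fold_groups == g).sum() == 2

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 1000))
    def test_random_groupings_never_split(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 40))
        groups = rng.integers(0, 8, size=n)
        if len(set(groups.tolist())) < 5:
            return
        split = kfold(n, k=5, seed=seed, groups=groups)
        seen = {}
        for i, fold in enumerate(split.test_folds):
            for g in groups[fold]:
                assert seen.setdefault(int(g), i) == i

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            kfold(3, k=5)

    def test_train_test_complementary(self):
        split = kfold(17, k=5, seed=2)
        for train, test in split:
            assert len(np.intersect1d(train, test)) == 0
            assert len(train) + len(test) == 17


class TestClusterSplit:
    def test_eighty_twenty_on_uniform_latents(self):
        rng = np.random.default_rng(0)
        latents = LatentMatrix(rng.standard_normal((100, 8)))
        train, test = cluster_split(latents, train_frac=0.8, seed=0)
        assert len(train) == 80 and len(test) == 20
        assert sorted(np.concatenate([train, test])) == list(range(100))

    def test_separated_blobs_stay_whole(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((30, 4)) * 0.01
        b = rng.standard_normal((30, 4)) * 0.01 + 100.0
        latents = LatentMatrix(np.vstack([a, b]))
        train, test = cluster_split(latents, train_frac=0.5, seed=0,
                                    n_clusters=2)
        # one blob per side: the test side is entirely one blob
        test_is_b = set(test.tolist())
        assert test_is_b == set(range(30)) or test_is_b == set(range(30, 60))

    def test_infeasible_fraction_rejected(self):
        latents = LatentMatrix(np.random.default_rng(0).standard_normal((10, 4)))
        with pytest.raises(ValueError):
            cluster_split(latents, train_frac=0.999)

    def test_deterministic(self):
        latents = LatentMatrix(np.random.default_rng(2).standard_normal((50, 6)))
        a = cluster_split(latents, seed=5)
        b = cluster_split(latents, seed=5)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])
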
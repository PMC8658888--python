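import numpy as np
import pytest

from crnnqsar.evaluation import kfold
from crnnqsar.synthetic import (SyntheticTaskSpec, augment_token_task,
                                make_isomer_pairs, make_task,
                                make_transfer_pair)


def _spec(**kw):
    defaults = dict(n=200, seq_len=10, vocab=6, seed=3, noise_sd=0.0)
    defaults.update(kw)
    return SyntheticTaskSpec(**defaults)


class TestMakeTask:
    def test_local_labels_permutation_invariant(self):
        task = make_task(_spec(label_mode="local"))
        rng = np.random.default_rng(0)
        # recompute labels after permuting every sequence: identical
        from crnnqsar.synthetic import _labels

        permuted = np.stack([s[rng.permutation(len(s))] for s in task.sequences])
        relabelled = _labels(permuted, task.weights, task.spec,
                             np.random.default_rng(0))
        np.testing.assert_allclose(np.sort(relabelled), np.sort(task.labels),
                                   atol=1e-10)

    def test_global_labels_change_under_permutation(self):
        task = make_task(_spec(label_mode="global", n=1000))
        from crnnqsar.synthetic import _components

        rng = np.random.default_rng(1)
        changed = 0
        for seq in task.sequences:
            perm = seq[rng.permutation(len(seq))]
            _, g0 = _components(seq[None, :], task.weights)
            _, g1 = _components(perm[None, :], task.weights)
            changed += abs(g0[0] - g1[0]) > 1e-12
        assert changed >= 990  # >= 99% of permutations move the order score

    def test_replayable(self):
        a = make_task(_spec(label_mode="mixed", noise_sd=0.3))
        b = make_task(_spec(label_mode="mixed", noise_sd=0.3))
        np.testing.assert_array_equal(a.sequences, b.sequences)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_labels_standardised(self):
        task = make_task(_spec(label_mode="mixed", noise_sd=0.0, n=2000))
        assert task.labels.mean() == pytest.approx(0.0, abs=1e-9)
        assert task.labels.std() == pytest.approx(1.0, abs=1e-9)

    def test_mixed_requires_both_weights(self):
        with pytest.raises(ValueError):
            _spec(label_mode="mixed", local_weight=0.0)


class TestIsomerPairs:
    def test_pair_structure(self):
        task = make_isomer_pairs(35, _spec(label_mode="global"))
        assert len(task) == 70
        assert len(set(task.groups.tolist())) == 35
        for i in range(35):
            a, b = task.sequences[2 * i], task.sequences[2 * i + 1]
            np.testing.assert_array_equal(np.sort(a), np.sort(b))  # same tokens
            assert not np.array_equal(a, b)  # different arrangement

    def test_order_blind_labelling_gives_equal_pairs(self):
        task = make_isomer_pairs(20, _spec(label_mode="local"))
        labels = task.labels.reshape(-1, 2)
        np.testing.assert_allclose(labels[:, 0], labels[:, 1], atol=1e-12)

    def test_order_sensitive_labelling_separates_pairs(self):
        task = make_isomer_pairs(20, _spec(label_mode="global"))
        labels = task.labels.reshape(-1, 2)
        assert np.all(np.abs(labels[:, 0] - labels[:, 1]) > 0)

    def test_grouped_cv_never_splits_pairs(self):
        task = make_isomer_pairs(35, _spec(label_mode="global"))
        split = kfold(len(task), k=5, seed=0, groups=task.groups)
        for fold in split.test_folds:
            fold_groups = task.groups[fold]
            values, counts = np.unique(fold_groups, return_counts=True)
            assert np.all(counts == 2)

    def test_short_sequences_rejected(self):
        with pytest.raises(ValueError):
            make_isomer_pairs(5, _spec(seq_len=1, label_mode="global"))


class TestTransferPairs:
    def test_full_relatedness_copies_local_rule(self):
        source, target = make_transfer_pair(_spec(label_mode="mixed"), 1.0)
        np.testing.assert_allclose(source.weights.w_local,
                                   target.weights.w_local, atol=1e-12)

    def test_zero_relatedness_decorrelates(self):
        corrs = []
        for seed in range(20):
            source, target = make_transfer_pair(
                _spec(label_mode="mixed", seed=seed), 0.0)
            corrs.append(np.corrcoef(source.weights.w_local,
                                     target.weights.w_local)[0, 1])
        assert abs(np.mean(corrs)) < 0.2

    def test_source_identical_across_relatedness(self):
        spec = _spec(label_mode="mixed")
        s1, _ = make_transfer_pair(spec, 0.8)
        s2, _ = make_transfer_pair(spec, 0.0)
        np.testing.assert_array_equal(s1.sequences, s2.sequences)
        np.testing.assert_array_equal(s1.labels, s2.labels)

    def test_target_is_small(self):
        _, target = make_transfer_pair(_spec(label_mode="mixed"), 0.5,
                                       n_target=150)
        assert len(target) == 150


class TestAugmentTokens:
    def test_expansion_and_label_replication(self):
        task = make_task(_spec(label_mode="local"))
        aug = augment_token_task(task, n_extra=9, seed=0)
        assert len(aug) == 10 * len(task)
        np.testing.assert_array_equal(aug.labels[:10], np.repeat(task.labels[0], 10))

    def test_augmented_rows_preserve_composition(self):
        task = make_task(_spec(label_mode="local", n=20))
        aug = augment_token_task(task, n_extra=4, seed=1)
        for i in range(20):
            base = np.sort(task.sequences[i])
            for j in range(5):
                np.testing.assert_array_equal(np.sort(aug.sequences[5 * i + j]), base)
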
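import numpy as np
import pytest

from crnnqsar.crnn_model import build_cnn, build_crnn, clone_config
from crnnqsar.data_io import Task
from crnnqsar.errors import ConfigurationError, DataError
from crnnqsar.evaluation import kfold, score_predictions
from crnnqsar.training import PhasePlan
from crnnqsar.transfer import (Checkpoint, TransferScheme, fine_tune,
                               pretrain_source, transfer_vs_scratch)

FAST = {"plan": PhasePlan(phases=[(frozenset({"conv", "gru", "dense"}), 2)])}


@pytest.fixture
def source_data():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((60, 32))
    y = X[:, :4].sum(axis=1) + 0.1 * rng.standard_normal(60)
    return X, y


@pytest.fixture
def target_data():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((40, 32))
    y = X[:, :4].sum(axis=1) + 0.1 * rng.standard_normal(40)
    return X, y


@pytest.fixture
def checkpoint(source_data, tiny_config):
    return pretrain_source(source_data, tiny_config, seed=0,
                           trainer_kwargs=FAST)


class TestPretrain:
    def test_five_fold_metrics_and_argmax(self, source_data, tiny_config):
        ckpt = pretrain_source(source_data, tiny_config, seed=0,
                               trainer_kwargs=FAST)
        assert len(ckpt.fold_metrics) == 5
        assert ckpt.val_metric == max(ckpt.fold_metrics)

    def test_constant_labels_rejected(self, tiny_config):
        X = np.random.default_rng(0).standard_normal((60, 32))
        with pytest.raises(DataError):
            pretrain_source((X, np.ones(60)), tiny_config, seed=0)

    def test_source_floor(self, tiny_config):
        X = np.random.default_rng(0).standard_normal((20, 32))
        with pytest.raises(DataError):
            pretrain_source((X, np.arange(20.0)), tiny_config, seed=0)

    def test_reloaded_checkpoint_reproduces_metric(self, source_data,
                                                   tiny_config, tmp_path):
        ckpt = pretrain_source(source_data, tiny_config, seed=0,
                               trainer_kwargs=FAST)
        path = tmp_path / "src.npz"
        ckpt.save(path)
        reloaded = Checkpoint.load(path)
        X, y = source_data
        best_fold = int(np.argmax(ckpt.fold_metrics))
        _, val_idx = list(kfold(len(y), k=5, seed=0))[best_fold]
        state = reloaded.restore()
        from crnnqsar.crnn_model import predict_scores

        metric = score_predictions(tiny_config.task, y[val_idx],
                                   predict_scores(state, X[val_idx]))
        assert metric == pytest.approx(ckpt.val_metric, abs=1e-6)


class TestFineTuneFreezeContracts:
    def _ft(self, ckpt, data, scheme, cfg, **kw):
        defaults = dict(seed=1, stage1_epochs=2, stage2_epochs=2)
        defaults.update(kw)
        return fine_tune(ckpt, data, scheme, cfg, **defaults)

    def test_conv_frozen_throughout_is_bitwise(self, checkpoint, target_data,
                                               tiny_config):
        state, _ = self._ft(checkpoint, target_data,
                            TransferScheme.conv_frozen_throughout, tiny_config)
        for name, p in state.model.store.params.items():
            if state.model.store.groups[name] == "conv":
                np.testing.assert_array_equal(
                    p.data, checkpoint.arrays[f"param:{name}"])

    def test_gru_frozen_throughout_is_bitwise(self, checkpoint, target_data,
                                              tiny_config):
        state, _ = self._ft(checkpoint, target_data,
                            TransferScheme.gru_frozen_throughout, tiny_config)
        for name, p in state.model.store.params.items():
            if state.model.store.groups[name] == "gru":
                np.testing.assert_array_equal(
                    p.data, checkpoint.arrays[f"param:{name}"])

    def test_conv_freeze_then_full_eventually_moves_conv(self, checkpoint,
                                                         target_data,
                                                         tiny_config):
        state, _ = self._ft(checkpoint, target_data,
                            TransferScheme.conv_freeze_then_full, tiny_config)
        moved = any(
            not np.array_equal(p.data, checkpoint.arrays[f"param:{name}"])
            for name, p in state.model.store.params.items()
            if state.model.store.groups[name] == "conv")
        assert moved

    def test_zero_epochs_preserves_everything_but_head(self, checkpoint,
                                                       target_data, tiny_config):
        state, _ = self._ft(checkpoint, target_data,
                            TransferScheme.conv_frozen_throughout, tiny_config,
                            stage1_epochs=0, stage2_epochs=0)
        for name, p in state.model.store.params.items():
            if not name.startswith("head."):
                np.testing.assert_array_equal(
                    p.data, checkpoint.arrays[f"param:{name}"])

    def test_cnn_checkpoint_rejected(self, target_data, tiny_config):
        cnn = build_cnn(tiny_config, seed=0)
        ckpt = Checkpoint(arrays=cnn.store_arrays
                          if hasattr(cnn, "store_arrays")
                          else cnn.model.store.state_arrays(),
                          config=tiny_config)
        with pytest.raises(ConfigurationError):
            fine_tune(ckpt, target_data, TransferScheme.gru_frozen_throughout,
                      tiny_config, seed=0)

    def test_latent_dim_mismatch_rejected(self, checkpoint, target_data):
        bad_cfg = clone_config(checkpoint.config, latent_dim=64)
        with pytest.raises(ConfigurationError):
            fine_tune(checkpoint, target_data,
                      TransferScheme.conv_frozen_throughout, bad_cfg, seed=0)

    def test_task_change_reshapes_head(self, checkpoint, target_data,
                                       tiny_config):
        Xt, yt = target_data
        cls_cfg = clone_config(tiny_config, task=Task.classification)
        state, report = self._ft(checkpoint, (Xt, (yt > 0).astype(float)),
                                 TransferScheme.conv_frozen_throughout, cls_cfg)
        assert state.model.store.params["head.w"].shape[1] == 2
        assert report.metric == "roc_auc"


class TestTransferVsScratch:
    def test_warm_start_on_same_distribution_not_worse(self, source_data,
                                                       tiny_config):
        full = frozenset({"conv", "gru", "dense"})
        cfg = clone_config(tiny_config, lr_conv=3e-3, lr_gru=3e-3,
                           lr_dense=3e-3)
        cmp = transfer_vs_scratch(
            source_data, source_data, TransferScheme.conv_freeze_then_full,
            cfg, seeds=[0, 1, 2],
            pretrain_kwargs={"trainer_kwargs": {
                "plan": PhasePlan(phases=[(full, 15)])}},
            finetune_kwargs={"stage1_epochs": 5, "stage2_epochs": 10,
                             "trainer_kwargs": {}},
            scratch_kwargs={"trainer_kwargs": {
                "plan": PhasePlan(phases=[(full, 15)])}})
        assert cmp.mean_finetuned >= cmp.mean_scratch

    def test_needs_three_seeds(self, source_data, target_data, tiny_config):
        with pytest.raises(ConfigurationError):
            transfer_vs_scratch(source_data, target_data,
                                TransferScheme.conv_freeze_then_full,
                                tiny_config, seeds=[0, 1])
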
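"""Transfer learning by parameter-group freezing.

A source model is pretrained with 5-fold cross-validation and the best fold
model is checkpointed.  Fine-tuning on a small target dataset then follows
one of three schemes:

* ``conv_freeze_then_full`` — stage 1 trains the GRU and dense groups with
  the conv group frozen, stage 2 unfreezes everything and fine-tunes the
  whole network;
* ``conv_frozen_throughout`` — the conv (local-feature) group is never
  unfrozen;
* ``gru_frozen_throughout`` — the GRU (global-feature) group stays frozen
  for the whole fine-tuning run.

Freezing is exact: a frozen group's parameters are bitwise identical to the
checkpoint afterwards.  The output head is always reinitialised before
fine-tuning, since source and target label scales generally differ.
Which source is *related* to which target is the caller's decision (in the
real setting that judgement comes from external evidence such as
binding-site similarity); the package only provides the machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .crnn_model import (CRNNConfig, TrainState, build_cnn, build_crnn,
                         clone_config, predict_scores)
from .data_io import EvalReport, Task, load_checkpoint, save_checkpoint, sem
from .errors import ConfigurationError, DataError
from .evaluation import kfold, score_predictions, task_metric
from .training import PhasePlan, train_three_phase

DEFAULT_SOURCE_FLOOR = 50


class TransferScheme(str, Enum):
    conv_freeze_then_full = "conv_freeze_then_full"
    conv_frozen_throughout = "conv_frozen_throughout"
    gru_frozen_throughout = "gru_frozen_throughout"


@dataclass
class Checkpoint:
    """A pretrained model: parameter arrays, config, and its validation metric."""

    arrays: dict
    config: CRNNConfig
    val_metric: float | None = None
    fold_metrics: list | None = None

    def save(self, path) -> None:
        class _StoreView:
            def __init__(self, arrays):
                self._arrays = arrays

            def state_arrays(self):
                return self._arrays

        save_checkpoint(path, _StoreView(self.arrays), self.config)

    @classmethod
    def load(cls, path) -> "Checkpoint":
        arrays, config = load_checkpoint(path)
        return cls(arrays=arrays, config=config)

    @property
    def kind(self) -> str:
        return "crnn" if any(k.startswith("param:gru") for k in self.arrays) \
            else "cnn"

    def restore(self, seed: int = 0) -> TrainState:
        state = build_crnn(self.config, seed) if self.kind == "crnn" else \
            build_cnn(self.config, seed)
        state.model.store.load_state_arrays(self.arrays)
        return state


def _check_not_degenerate(y: np.ndarray, task: Task) -> None:
    if Task(task) is Task.classification:
        if len(np.unique(y)) < 2:
            raise DataError("source labels contain a single class")
    elif np.var(y) == 0:
        raise DataError("source labels have zero variance")


def pretrain_source(source_data, config: CRNNConfig, seed: int = 0,
                    k: int = 5, min_size: int = DEFAULT_SOURCE_FLOOR,
                    trainer_kwargs: dict | None = None) -> Checkpoint:
    """Train k fold models on the source task and checkpoint the best one.

    `source_data` is an (X, y) pair of latent vectors and labels.  Fold
    model selection is by validation metric, deterministic given the seed.
    """
    X, y = np.asarray(source_data[0]), np.asarray(source_data[1])
    if len(y) < min_size:
        raise DataError(f"source dataset too small ({len(y)} < {min_size})")
    _check_not_degenerate(y, config.task)
    trainer_kwargs = dict(trainer_kwargs or {})
    split = kfold(len(y), k=k, seed=seed)
    best = None
    fold_metrics = []
    for fold_i, (train_idx, val_idx) in enumerate(split):
        state = build_crnn(config, seed=seed * 1000 + fold_i)
        state, _ = train_three_phase(
            state, (X[train_idx], y[train_idx]), (X[val_idx], y[val_idx]),
            config, seed=seed * 1000 + fold_i, **trainer_kwargs)
        metric = score_predictions(config.task, y[val_idx],
                                   predict_scores(state, X[val_idx]))
        fold_metrics.append(metric)
        if best is None or metric > best[0]:
            best = (metric, state.model.store.state_arrays())
    arrays = {name: arr.copy() for name, arr in best[1].items()}
    return Checkpoint(arrays=arrays, config=config, val_metric=best[0],
                      fold_metrics=fold_metrics)


def _scheme_plan(scheme: TransferScheme, stage1_epochs: int,
                 stage2_epochs: int) -> PhasePlan:
    if scheme is TransferScheme.conv_freeze_then_full:
        return PhasePlan(phases=[
            (frozenset({"gru", "dense"}), stage1_epochs),
            (frozenset({"conv", "gru", "dense"}), stage2_epochs),
        ])
    if scheme is TransferScheme.conv_frozen_throughout:
        return PhasePlan(phases=[(frozenset({"gru", "dense"}),
                                  stage1_epochs + stage2_epochs)])
    return PhasePlan(phases=[(frozenset({"conv", "dense"}),
                              stage1_epochs + stage2_epochs)])


def fine_tune(checkpoint: Checkpoint, target_data, scheme: TransferScheme,
              config: CRNNConfig | None = None, seed: int = 0,
              val_frac: float = 0.2, stage1_epochs: int = 50,
              stage2_epochs: int = 100, stage2_lr_scale: float | None = None,
              trainer_kwargs: dict | None = None):
    """Fine-tune a pretrained model on target data under one freeze scheme.

    Returns (TrainState, EvalReport) where the report holds the held-out
    validation metric of the fine-tuned model.  `stage2_lr_scale` optionally
    shrinks all learning rates in the unfrozen stage of
    ``conv_freeze_then_full`` (off by default).
    """
    scheme = TransferScheme(scheme)
    config = config if config is not None else checkpoint.config
    if config.latent_dim != checkpoint.config.latent_dim:
        raise ConfigurationError("checkpoint latent_dim does not match target config")
    state = checkpoint.restore(seed=seed)
    groups = state.model.store.group_names()
    if "gru" not in groups:
        raise ConfigurationError(f"scheme {scheme.value} needs a model with a GRU group")
    state.model.config = config
    state.model.reinit_head(seed)  # target label scale differs from the source's
    X, y = np.asarray(target_data[0]), np.asarray(target_data[1])
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    n_val = max(1, int(round(val_frac * len(y))))
    val_idx, train_idx = order[:n_val], order[n_val:]
    trainer_kwargs = dict(trainer_kwargs or {})
    plan = _scheme_plan(scheme, stage1_epochs, stage2_epochs)
    if scheme is TransferScheme.conv_freeze_then_full and stage2_lr_scale:
        # run the two stages with separate optimizers so stage-2 rates shrink
        state, hist1 = train_three_phase(
            state, (X[train_idx], y[train_idx]), (X[val_idx], y[val_idx]), config,
            plan=PhasePlan(phases=plan.phases[:1]), seed=seed, **trainer_kwargs)
        scaled = clone_config(config,
                              lr_conv=config.lr_conv * stage2_lr_scale,
                              lr_gru=config.lr_gru * stage2_lr_scale,
                              lr_dense=config.lr_dense * stage2_lr_scale)
        state, hist2 = train_three_phase(
            state, (X[train_idx], y[train_idx]), (X[val_idx], y[val_idx]), scaled,
            plan=PhasePlan(phases=plan.phases[1:]), seed=seed + 1, **trainer_kwargs)
    else:
        state, _ = train_three_phase(
            state, (X[train_idx], y[train_idx]), (X[val_idx], y[val_idx]), config,
            plan=plan, seed=seed, **trainer_kwargs)
    metric = score_predictions(config.task, y[val_idx],
                               predict_scores(state, X[val_idx]))
    report = EvalReport(per_fold=[metric], metric=task_metric(config.task))
    return state, report


@dataclass
class TransferComparison:
    """Fine-tuned vs from-scratch target performance across seeds."""

    scheme: TransferScheme
    finetuned: list
    scratch: list

    @property
    def mean_finetuned(self) -> float:
        return float(np.mean(self.finetuned))

    @property
    def mean_scratch(self) -> float:
        return float(np.mean(self.scratch))

    @property
    def sem_finetuned(self) -> float:
        return sem(self.finetuned)

    @property
    def sem_scratch(self) -> float:
        return sem(self.scratch)

    @property
    def improvement(self) -> float:
        return self.mean_finetuned - self.mean_scratch

    @property
    def improvement_pct(self) -> float:
        base = abs(self.mean_scratch)
        return 100.0 * self.improvement / base if base > 0 else float("inf")

    def paired_t(self) -> float:
        """Paired t statistic of the per-seed improvement (0 if degenerate)."""
        d = np.asarray(self.finetuned) - np.asarray(self.scratch)
        if len(d) < 2 or d.std(ddof=1) == 0:
            return 0.0
        return float(d.mean() / (d.std(ddof=1) / np.sqrt(len(d))))


def train_scratch(target_data, config: CRNNConfig, seed: int = 0,
                  val_frac: float = 0.2,
                  trainer_kwargs: dict | None = None) -> float:
    """From-scratch CRNN baseline on the target, same split as fine_tune."""
    X, y = np.asarray(target_data[0]), np.asarray(target_data[1])
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    n_val = max(1, int(round(val_frac * len(y))))
    val_idx, train_idx = order[:n_val], order[n_val:]
    state = build_crnn(config, seed=seed)
    state, _ = train_three_phase(state, (X[train_idx], y[train_idx]),
                                 (X[val_idx], y[val_idx]), config, seed=seed,
                                 **(trainer_kwargs or {}))
    return score_predictions(config.task, y[val_idx],
                             predict_scores(state, X[val_idx]))


def transfer_vs_scratch(source_data, target_data, scheme: TransferScheme,
                        config: CRNNConfig, seeds, checkpoints=None,
                        pretrain_kwargs: dict | None = None,
                        finetune_kwargs: dict | None = None,
                        scratch_kwargs: dict | None = None) -> TransferComparison:
    """Compare fine-tuned vs from-scratch target performance over >= 3 seeds.

    `checkpoints` may supply pretrained source models (one per seed) so
    several schemes and targets can reuse the same pretraining runs.
    """
    seeds = list(seeds)
    if len(seeds) < 3:
        raise ConfigurationError("transfer_vs_scratch needs at least 3 seeds")
    scheme = TransferScheme(scheme)
    finetuned, scratch = [], []
    for i, seed in enumerate(seeds):
        ckpt = checkpoints[i] if checkpoints is not None else pretrain_source(
            source_data, config, seed=seed, **(pretrain_kwargs or {}))
        _, report = fine_tune(ckpt, target_data, scheme, config, seed=seed,
                              **(finetune_kwargs or {}))
        finetuned.append(report.mean)
        scratch.append(train_scratch(target_data, config, seed=seed,
                                     **(scratch_kwargs or {})))
    return TransferComparison(scheme=scheme, finetuned=finetuned, scratch=scratch)
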
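"""Training protocols: batch-size rule, early stopping, the 3-phase
schedule and the hyperparameter grid-search harness.

The 3-phase protocol stabilises CRNN training: phase 1 updates the conv and
dense groups with the GRU frozen, phase 2 trains the GRU alone, phase 3
fine-tunes all three groups jointly.  Freezing is exact — a frozen group is
excluded from the optimizer, so its parameters are bitwise unchanged, and
its batch-norm running statistics are likewise not updated.

Early stopping monitors the validation metric (r^2 for regression, ROC-AUC
for classification): a drop of more than `threshold` below the best seen
counts as a qualifying decrease, a new best resets the counter, and
training stops at the `patience_limit`-th qualifying decrease (default 3,
i.e. stopping triggers once the metric has decreased more than 2 times).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .crnn_model import (CRNNConfig, TrainState, build_cnn, build_crnn,
                         default_conv_stack, predict_scores)
from .data_io import Task
from .errors import ConfigurationError
from .evaluation import score_predictions
from .nn.autograd import mse_loss, softmax_cross_entropy
from .nn.optim import Adam

logger = logging.getLogger(__name__)

EARLY_STOP_THRESHOLDS = (0.005, 0.01)

# Table-1-style hyperparameter search domains
GRID_DOMAIN = {
    "activation_conv": ("tanh", "relu"),
    "activation_gru_body": ("sigmoid", "relu"),
    "lr_conv": (0.001, 0.0005, 0.0001),
    "lr_gru": (0.001, 0.0005, 0.0001),
    "n_conv_layers": (3, 4, 5),
    "gru_layers": (1, 2),
}


def select_batch_size(dataset_size: int) -> int:
    """Dataset-size-dependent batch size: >=300 -> 128; 101..299 -> 64; <=100 -> 24."""
    if dataset_size < 1:
        raise ValueError("dataset size must be positive")
    if dataset_size >= 300:
        return 128
    if dataset_size > 100:
        return 64
    return 24


@dataclass
class EarlyStopState:
    threshold: float = 0.01
    best_metric: float = -math.inf
    decrease_count: int = 0
    patience_limit: int = 3
    stopped: bool = False


def early_stop_update(state: EarlyStopState, new_metric: float) -> EarlyStopState:
    """Pure update of the early-stopping counter with a new validation metric."""
    if not math.isfinite(new_metric):
        raise ValueError(f"non-finite validation metric: {new_metric}")
    best = state.best_metric
    count = state.decrease_count
    if new_metric > best:
        best = new_metric
        count = 0
    elif new_metric < state.best_metric - state.threshold:
        count += 1
    return replace(state, best_metric=best, decrease_count=count,
                   stopped=count >= state.patience_limit)


@dataclass
class PhasePlan:
    """Ordered training phases: (trainable group set, max epochs)."""

    phases: list = field(default_factory=lambda: [
        (frozenset({"conv", "dense"}), 50),
        (frozenset({"gru"}), 50),
        (frozenset({"conv", "gru", "dense"}), 100),
    ])

    @classmethod
    def single(cls, groups, max_epochs: int) -> "PhasePlan":
        return cls(phases=[(frozenset(groups), max_epochs)])


def _loss(state: TrainState, X: np.ndarray, y: np.ndarray, update_stats: bool):
    out = state.model.forward(X, train=True, update_stats=update_stats)
    if state.config.task is Task.classification:
        return softmax_cross_entropy(out, y.astype(int))
    return mse_loss(out[:, 0], y)


def _validation_metric(state: TrainState, val_data) -> float:
    X, y = val_data
    return score_predictions(state.config.task, y, predict_scores(state, X))


def _run_epochs(state: TrainState, optimizer: Adam, groups: frozenset,
                train_data, val_data, max_epochs: int, batch_size: int,
                rng: np.random.Generator, threshold: float, patience: int,
                history: list, phase_index: int) -> TrainState:
    groups = frozenset(groups)
    if not groups:
        raise ConfigurationError("phase must train at least one parameter group")
    unknown = groups - state.model.store.group_names()
    if unknown:
        raise ConfigurationError(f"unknown parameter groups: {sorted(unknown)}")
    state.set_trainable(groups)
    X, y = train_data
    n = len(y)
    update_stats = "conv" in groups and state.config.use_batchnorm
    es = EarlyStopState(threshold=threshold, patience_limit=patience)
    for _ in range(max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            state.model.store.zero_grad()
            loss = _loss(state, X[idx], y[idx], update_stats)
            loss.backward()
            optimizer.step(groups)
        state.epoch += 1
        if val_data is not None:
            metric = _validation_metric(state, val_data)
            history.append({"phase": phase_index, "epoch": state.epoch,
                            "val_metric": metric})
            es = early_stop_update(es, metric)
            if state.best_metric is None or metric > state.best_metric:
                state.best_metric = metric
            if es.stopped:
                break
    return state


def train_single_phase(state: TrainState, groups, data, config: CRNNConfig,
                       val_data=None, max_epochs: int = 1, seed: int = 0,
                       batch_size: int | None = None, threshold: float = 0.01,
                       patience: int = 3, optimizer: Adam | None = None) -> TrainState:
    """Train only the given parameter groups; all other groups stay bitwise fixed."""
    X, y = data
    if batch_size is None:
        batch_size = select_batch_size(len(y))
    if optimizer is None:
        optimizer = Adam(state.model.store, config.group_lrs)
    rng = np.random.default_rng(seed)
    history: list = []
    return _run_epochs(state, optimizer, frozenset(groups), (np.asarray(X), np.asarray(y)),
                       val_data, max_epochs, batch_size, rng, threshold, patience,
                       history, phase_index=0)


def train_three_phase(state: TrainState, train_data, val_data, config: CRNNConfig,
                      plan: PhasePlan | None = None, seed: int = 0,
                      batch_size: int | None = None, threshold: float = 0.01,
                      patience: int = 3):
    """Run the ordered phase plan with one persistent per-group Adam optimizer.

    Returns (state, history); history rows carry the phase index, so phase
    boundaries are visible.  Validation is monitored (and early stopping
    applied) within each phase.
    """
    X, y = train_data
    X = np.asarray(X)
    y = np.asarray(y)
    if val_data is not None:
        Xv = np.asarray(val_data[0])
        if Xv.shape[0] == X.shape[0] and np.array_equal(Xv, X):
            logger.warning("validation data appears identical to training data")
    if plan is None:
        plan = PhasePlan()
    if batch_size is None:
        batch_size = select_batch_size(len(y))
    optimizer = Adam(state.model.store, config.group_lrs)
    rng = np.random.default_rng(seed)
    history: list = []
    for phase_index, (groups, max_epochs) in enumerate(plan.phases):
        state = _run_epochs(state, optimizer, groups, (X, y), val_data,
                            max_epochs, batch_size, rng, threshold, patience,
                            history, phase_index)
    return state, history


def train_single_phase_run(state: TrainState, train_data, val_data,
                           config: CRNNConfig, max_epochs: int = 200,
                           seed: int = 0, batch_size: int | None = None,
                           threshold: float = 0.01, patience: int = 3, **_ignored):
    """End-to-end from-scratch training of all groups (the CNN protocol;
    also the from-scratch CRNN baseline for transfer comparisons)."""
    groups = state.model.store.group_names()
    plan = PhasePlan.single(groups, max_epochs)
    return train_three_phase(state, train_data, val_data, config, plan=plan,
                             seed=seed, batch_size=batch_size,
                             threshold=threshold, patience=patience)


def _grid_configs(grid: dict, base: CRNNConfig):
    keys = list(grid.keys())
    for key in keys:
        domain = GRID_DOMAIN.get(key)
        if domain is None:
            raise ConfigurationError(f"unknown grid axis {key!r}")
        for value in grid[key]:
            if value not in domain:
                logger.warning("grid value %r outside the usual domain for %s",
                               value, key)
    for combo in itertools.product(*(grid[k] for k in keys)):
        overrides = dict(zip(keys, combo))
        n_layers = overrides.pop("n_conv_layers", None)
        if n_layers is not None:
            kernels, filters = default_conv_stack(n_layers)
            overrides.update(n_conv_layers=n_layers, conv_kernels=kernels,
                             conv_filters=filters)
        yield replace(base, **overrides)


def grid_search(train_data, val_data, grid: dict, base_config: CRNNConfig,
                seed: int = 0, model: str = "crnn",
                trainer_kwargs: dict | None = None) -> CRNNConfig:
    """Exhaustive search over the Cartesian grid; argmax validation metric.

    Ties break deterministically to the first configuration in enumeration
    order.  `grid` maps a subset of {activation_conv, activation_gru_body,
    lr_conv, lr_gru, n_conv_layers, gru_layers} to candidate values.
    """
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ConfigurationError("grid must be a nonempty mapping of nonempty lists")
    trainer_kwargs = dict(trainer_kwargs or {})
    best_cfg = None
    best_metric = -math.inf
    for cfg in _grid_configs(grid, base_config):
        if model == "cnn":
            state = build_cnn(cfg, seed=seed)
            state, _ = train_single_phase_run(state, train_data, val_data, cfg,
                                              seed=seed, **trainer_kwargs)
        else:
            state = build_crnn(cfg, seed=seed)
            state, _ = train_three_phase(state, train_data, val_data, cfg,
                                         seed=seed, **trainer_kwargs)
        metric = _validation_metric(state, val_data)
        if metric > best_metric:
            best_metric = metric
            best_cfg = cfg
    return best_cfg
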
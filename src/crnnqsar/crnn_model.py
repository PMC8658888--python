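"""The conv -> bidirectional GRU -> dense QSAR architecture and its CNN ablation.

A molecular latent vector is treated as a length-`latent_dim`,
single-channel 1-D signal.  Three convolution blocks (valid convolution,
stride 1, kernel sizes 5/2/5, filter counts 15/30/60, each followed by
batch normalisation and the configured activation) extract local features;
a single max-pool (window 2) follows the last block.  The pooled feature
map is summarised either by a bidirectional GRU (CRNN — final hidden states
of both directions concatenated) or by global average pooling over
positions (CNN ablation), and fed through two fully connected layers ending
in a 2-unit softmax head (classification) or a 1-unit linear head
(regression).

Parameters are partitioned into three named groups — ``conv``, ``gru``,
``dense`` — which the 3-phase trainer and the transfer-learning schemes
freeze and unfreeze independently.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .data_io import LatentMatrix, Task
from .errors import ArchitectureError, ConfigurationError
from .nn.autograd import Tensor, batchnorm1d, conv1d, maxpool1d, relu, tanh
from .nn.layers import ParamStore, bigru_summary, init_gru, init_linear, uniform_init

_CONV_ACTS = {"relu": relu, "tanh": tanh}

# kernel/filter patterns for the 3-5 conv layer grid; the first three entries
# are the default stack
_KERNEL_PATTERN = (5, 2, 5, 2, 5)
_FILTER_PATTERN = (15, 30, 60, 60, 60)


def default_conv_stack(n_layers: int) -> tuple:
    if not 3 <= n_layers <= 5:
        raise ConfigurationError("n_conv_layers must be in 3..5")
    return _KERNEL_PATTERN[:n_layers], _FILTER_PATTERN[:n_layers]


@dataclass
class CRNNConfig:
    latent_dim: int = 512
    conv_kernels: tuple = (5, 2, 5)
    conv_filters: tuple = (15, 30, 60)
    n_conv_layers: int = 3
    use_batchnorm: bool = True
    pool_size: int = 2
    pool_type: str = "max"  # "max" | "avg"
    gru_layers: int = 1
    gru_bidirectional: bool = True
    gru_hidden: int = 64
    dense_hidden: int = 128
    task: Task = Task.regression
    activation_conv: str = "relu"       # "relu" | "tanh"
    activation_gru_body: str = "relu"   # candidate activation; gates stay sigmoid
    gru_relu_gates: bool = False        # also swap gate nonlinearity (non-default)
    lr_conv: float = 0.0001
    lr_gru: float = 0.0005
    lr_dense: float = 0.0001

    def __post_init__(self):
        self.task = Task(self.task)
        self.conv_kernels = tuple(self.conv_kernels)
        self.conv_filters = tuple(self.conv_filters)
        if not (self.n_conv_layers == len(self.conv_kernels) == len(self.conv_filters)):
            raise ConfigurationError(
                "n_conv_layers must match len(conv_kernels) and len(conv_filters)")

    @property
    def n_outputs(self) -> int:
        return 2 if self.task is Task.classification else 1

    @property
    def group_lrs(self) -> dict:
        return {"conv": self.lr_conv, "gru": self.lr_gru, "dense": self.lr_dense}


def config_to_dict(config: CRNNConfig) -> dict:
    d = asdict(config)
    d["task"] = config.task.value
    d["conv_kernels"] = list(config.conv_kernels)
    d["conv_filters"] = list(config.conv_filters)
    return d


def config_from_dict(d: dict) -> CRNNConfig:
    return CRNNConfig(**d)


def conv_output_length(config: CRNNConfig) -> int:
    """Sequence length after the conv stack and the single pool; raises if degenerate."""
    length = config.latent_dim
    for k in config.conv_kernels:
        length = length - k + 1
        if length <= 0:
            raise ArchitectureError(
                f"latent_dim={config.latent_dim} too small for kernels "
                f"{config.conv_kernels}")
    length = length // config.pool_size
    if length < 1:
        raise ArchitectureError("pooled feature map is empty")
    return length


class _Model:
    """Shared machinery of the CRNN and CNN variants."""

    kind = ""

    def __init__(self, config: CRNNConfig, seed: int):
        self.config = config
        self.store = ParamStore()
        rng = np.random.default_rng(seed)
        self._build(rng)

    # -- construction ----------------------------------------------------

    def _build_conv(self, rng) -> None:
        cfg = self.config
        in_ch = 1
        for i, (k, f) in enumerate(zip(cfg.conv_kernels, cfg.conv_filters)):
            fan_in = in_ch * k
            self.store.add_param(f"conv{i}.w", uniform_init(rng, (f, in_ch, k), fan_in), "conv")
            self.store.add_param(f"conv{i}.b", uniform_init(rng, (f,), fan_in), "conv")
            if cfg.use_batchnorm:
                self.store.add_param(f"conv{i}.bn.gamma", np.ones(f), "conv")
                self.store.add_param(f"conv{i}.bn.beta", np.zeros(f), "conv")
                self.store.add_buffer(f"conv{i}.bn.mean", np.zeros(f))
                self.store.add_buffer(f"conv{i}.bn.var", np.ones(f))
            in_ch = f

    def _build_dense(self, rng, summary_dim: int) -> None:
        cfg = self.config
        init_linear(self.store, rng, "dense0", summary_dim, cfg.dense_hidden, "dense")
        init_linear(self.store, rng, "head", cfg.dense_hidden, cfg.n_outputs, "dense")

    def reinit_head(self, seed: int) -> None:
        """Fresh output layer (used when transferring to a new task/label scale)."""
        rng = np.random.default_rng(seed)
        cfg = self.config
        fan_in = cfg.dense_hidden
        self.store.params["head.w"].data = uniform_init(
            rng, (fan_in, cfg.n_outputs), fan_in)
        self.store.params["head.b"].data = uniform_init(rng, (cfg.n_outputs,), fan_in)

    # -- forward ----------------------------------------------------------

    def _conv_trunk(self, x: Tensor, train: bool, update_stats: bool) -> Tensor:
        cfg = self.config
        act = _CONV_ACTS[cfg.activation_conv]
        h = x
        for i in range(cfg.n_conv_layers):
            h = conv1d(h, self.store.params[f"conv{i}.w"], self.store.params[f"conv{i}.b"])
            if cfg.use_batchnorm:
                h = batchnorm1d(h, self.store.params[f"conv{i}.bn.gamma"],
                                self.store.params[f"conv{i}.bn.beta"],
                                self.store.buffers[f"conv{i}.bn.mean"],
                                self.store.buffers[f"conv{i}.bn.var"],
                                train=train, update_stats=update_stats)
            h = act(h)
        if cfg.pool_type == "max":
            h = maxpool1d(h, cfg.pool_size)
        else:
            B, C, L = h.shape
            Lp = L // cfg.pool_size
            h = h[:, :, :Lp * cfg.pool_size].reshape(B, C, Lp, cfg.pool_size).mean(axis=3)
        return h

    def _dense_part(self, summary: Tensor) -> Tensor:
        p = self.store.params
        h = relu(summary @ p["dense0.w"] + p["dense0.b"])
        return h @ p["head.w"] + p["head.b"]

    def forward(self, latents: np.ndarray, train: bool = False,
                update_stats: bool | None = None) -> Tensor:
        cfg = self.config
        from .nn import autograd as _ag
        latents = np.asarray(latents, dtype=_ag.DTYPE)
        if latents.ndim != 2 or latents.shape[1] != cfg.latent_dim:
            raise ArchitectureError(
                f"expected (n, {cfg.latent_dim}) latents, got {latents.shape}")
        if update_stats is None:
            update_stats = train
        x = Tensor(latents.reshape(latents.shape[0], 1, cfg.latent_dim))
        feat = self._conv_trunk(x, train, update_stats)
        return self._dense_part(self._summary(feat))

    def _summary(self, feat: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class CRNNModel(_Model):
    kind = "crnn"

    def _build(self, rng):
        cfg = self.config
        conv_output_length(cfg)  # validate layer arithmetic early
        self._build_conv(rng)
        n_feat = cfg.conv_filters[-1]
        init_gru(self.store, rng, "gru0", n_feat, cfg.gru_hidden, cfg.gru_bidirectional)
        for layer in range(1, cfg.gru_layers):
            width = cfg.gru_hidden * (2 if cfg.gru_bidirectional else 1)
            init_gru(self.store, rng, f"gru{layer}", width, cfg.gru_hidden,
                     cfg.gru_bidirectional)
        summary_dim = cfg.gru_hidden * (2 if cfg.gru_bidirectional else 1)
        self._build_dense(rng, summary_dim)

    def _summary(self, feat: Tensor) -> Tensor:
        cfg = self.config
        h = feat
        for layer in range(cfg.gru_layers):
            last = layer == cfg.gru_layers - 1
            h = bigru_summary(h, self.store, f"gru{layer}", cfg.gru_hidden,
                              cfg.gru_bidirectional, cfg.activation_gru_body,
                              cfg.gru_relu_gates)
            if not last:
                # stacked GRUs need a sequence; broadcast the summary is wrong,
                # so intermediate layers would need full sequences.  With the
                # default single layer this branch never runs; for deeper
                # grids we re-shape the summary into a length-1 sequence.
                h = h.reshape(h.shape[0], h.shape[1], 1)
        return h


class CNNModel(_Model):
    """Ablation sharing the conv and dense specification, recurrent part removed.

    The pooled feature map is summarised by global average pooling over
    positions, an order-invariant reduction, before the dense part.  This
    keeps the CNN's parameter count below the CRNN's and makes the ablation
    a clean probe of order (global-feature) sensitivity.
    """

    kind = "cnn"

    def _build(self, rng):
        cfg = self.config
        conv_output_length(cfg)
        self._build_conv(rng)
        self._build_dense(rng, cfg.conv_filters[-1])

    def _summary(self, feat: Tensor) -> Tensor:
        return feat.mean(axis=2)


@dataclass
class TrainState:
    """A model plus per-group trainability flags and training bookkeeping."""

    model: _Model
    trainable: dict = field(default_factory=dict)
    epoch: int = 0
    best_metric: float | None = None

    def __post_init__(self):
        if not self.trainable:
            self.trainable = {g: True for g in self.model.store.group_names()}

    @property
    def config(self) -> CRNNConfig:
        return self.model.config

    def trainable_groups(self) -> set:
        return {g for g, on in self.trainable.items() if on}

    def set_trainable(self, groups) -> None:
        groups = set(groups)
        unknown = groups - self.model.store.group_names()
        if unknown:
            raise ConfigurationError(f"unknown parameter groups: {sorted(unknown)}")
        self.trainable = {g: g in groups for g in self.model.store.group_names()}

    def group_snapshot(self, group: str) -> dict:
        return {n: p.data.copy() for n, p in self.model.store.params.items()
                if self.model.store.groups[n] == group}


def build_crnn(config: CRNNConfig, seed: int = 0) -> TrainState:
    return TrainState(CRNNModel(config, seed))


def build_cnn(config: CRNNConfig, seed: int = 0) -> TrainState:
    return TrainState(CNNModel(config, seed))


def forward(state: TrainState, latents) -> np.ndarray:
    """Evaluation-mode forward pass.

    Classification: (n, 2) class scores (logits).  Regression: (n,) reals.
    Uses running batch-norm statistics, so the output of a row is
    independent of batch composition and order.
    """
    if isinstance(latents, LatentMatrix):
        latents = latents.values
    out = state.model.forward(latents, train=False).data
    if state.config.task is Task.regression:
        return out[:, 0]
    return out


def predict_scores(state: TrainState, latents) -> np.ndarray:
    """Class-1 probability (classification) or raw prediction (regression)."""
    out = forward(state, latents)
    if state.config.task is Task.classification:
        z = out - out.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return ez[:, 1] / ez.sum(axis=1)
    return out


def clone_config(config: CRNNConfig, **overrides) -> CRNNConfig:
    return replace(config, **overrides)
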
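"""Synthetic sequence-regression tasks with controllable local/global structure.

Items are abstract integer token sequences, not chemically valid SMILES:
that is what guarantees exact control over composition versus order.  The
label of a sequence is built from two hidden, seed-derived scoring rules:

* a *local* (composition) score — a weighted token count, invariant under
  any within-sequence permutation, standing in for "which atoms and
  functional groups are present";
* a *global* (order) score — a position-weighted token score with centred
  position weights, standing in for "how the atoms are arranged"; a random
  permutation of a sequence changes it almost surely.

Each component is z-scored across the dataset, combined with the requested
weights, re-standardised, and Gaussian noise is added.  Because labels are
standardised before noise, r^2 values are comparable across specs.

"Isomer" pairs — a sequence plus a non-identical random permutation of it,
sharing a group id — probe global-feature learning: composition is
identical within a pair, so any within-pair label difference is pure order
information.  Transfer pairs share hidden *local* weights between source
and target with a chosen correlation (the relatedness knob, emulating how
similar two assay targets are), while their global weights are independent;
the source task is identical for every relatedness value, so one pretrained
source model can be reused across relatedness conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np


class LabelMode(str, Enum):
    local = "local"
    global_ = "global"
    mixed = "mixed"


@dataclass
class SyntheticTaskSpec:
    n: int = 500
    seq_len: int = 40
    vocab: int = 12
    label_mode: LabelMode = LabelMode.mixed
    local_weight: float = 1.0
    global_weight: float = 1.0
    noise_sd: float = 0.3
    seed: int = 0
    relatedness: float = 1.0

    def __post_init__(self):
        self.label_mode = LabelMode(self.label_mode)
        if self.local_weight < 0 or self.global_weight < 0:
            raise ValueError("component weights must be non-negative")
        if self.label_mode is LabelMode.mixed and (
                self.local_weight <= 0 or self.global_weight <= 0):
            raise ValueError("mixed mode requires both weights > 0")
        if not 0.0 <= self.relatedness <= 1.0:
            raise ValueError("relatedness must be in [0, 1]")

    @property
    def effective_weights(self) -> tuple:
        if self.label_mode is LabelMode.local:
            return self.local_weight, 0.0
        if self.label_mode is LabelMode.global_:
            return 0.0, self.global_weight
        return self.local_weight, self.global_weight


@dataclass
class HiddenWeights:
    """Seed-derived scoring rules defining a task's labelling function."""

    w_local: np.ndarray   # (vocab,) token composition weights
    w_pos: np.ndarray     # (seq_len,) centred position weights
    w_tok: np.ndarray     # (vocab,) token weights of the order score


@dataclass
class TokenTask:
    """A synthetic dataset: (n, seq_len) int sequences with real labels."""

    sequences: np.ndarray
    labels: np.ndarray
    spec: SyntheticTaskSpec
    groups: np.ndarray | None = None
    weights: HiddenWeights = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.labels)


def _hidden_weights(spec: SyntheticTaskSpec, stream: int = 1) -> HiddenWeights:
    rng = np.random.default_rng([spec.seed, stream])
    w_local = rng.standard_normal(spec.vocab)
    w_pos = rng.standard_normal(spec.seq_len)
    w_pos -= w_pos.mean()  # centred: a random permutation decorrelates the order score
    w_tok = rng.standard_normal(spec.vocab)
    return HiddenWeights(w_local=w_local, w_pos=w_pos, w_tok=w_tok)


def _components(sequences: np.ndarray, w: HiddenWeights) -> tuple:
    local = w.w_local[sequences].mean(axis=1)
    global_ = (w.w_pos[None, :] * w.w_tok[sequences]).mean(axis=1)
    return local, global_


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def _labels(sequences: np.ndarray, w: HiddenWeights, spec: SyntheticTaskSpec,
            noise_rng: np.random.Generator) -> np.ndarray:
    lw, gw = spec.effective_weights
    local, global_ = _components(sequences, w)
    signal = lw * _zscore(local) + gw * _zscore(global_)
    signal = _zscore(signal)
    if spec.noise_sd > 0:
        signal = signal + noise_rng.normal(0.0, spec.noise_sd, size=len(signal))
    return signal


def make_task(spec: SyntheticTaskSpec) -> TokenTask:
    """Sample a task: uniform random sequences, hidden-rule labels."""
    rng = np.random.default_rng([spec.seed, 0])
    sequences = rng.integers(0, spec.vocab, size=(spec.n, spec.seq_len))
    w = _hidden_weights(spec)
    labels = _labels(sequences, w, spec, np.random.default_rng([spec.seed, 2]))
    return TokenTask(sequences=sequences, labels=labels, spec=spec, weights=w)


def _nonidentical_permutation(seq: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    for _ in range(100):
        perm = rng.permutation(len(seq))
        out = seq[perm]
        if not np.array_equal(out, seq):
            return out
    return seq[::-1].copy()  # constant sequences have no distinct permutation


def make_isomer_pairs(n_pairs: int, spec: SyntheticTaskSpec) -> TokenTask:
    """Composition-preserving permutation pairs sharing a group id.

    Within a pair the token multiset is identical, so with zero noise any
    within-pair label difference is exactly the global (order) component.
    """
    if spec.seq_len < 2:
        raise ValueError("isomer pairs require seq_len >= 2")
    # an order-blind (local) labelling is permitted: it yields exactly equal
    # labels within each pair, the degenerate control case
    rng = np.random.default_rng([spec.seed, 0])
    base = rng.integers(0, spec.vocab, size=(n_pairs, spec.seq_len))
    sequences = np.empty((2 * n_pairs, spec.seq_len), dtype=base.dtype)
    groups = np.empty(2 * n_pairs, dtype=int)
    for i in range(n_pairs):
        sequences[2 * i] = base[i]
        sequences[2 * i + 1] = _nonidentical_permutation(base[i], rng)
        groups[2 * i] = groups[2 * i + 1] = i
    w = _hidden_weights(spec)
    labels = _labels(sequences, w, spec, np.random.default_rng([spec.seed, 2]))
    return TokenTask(sequences=sequences, labels=labels, spec=spec,
                     groups=groups, weights=w)


def make_transfer_pair(spec: SyntheticTaskSpec, relatedness: float | None = None,
                       n_target: int = 150) -> tuple:
    """A large source task and a small target task with correlated rules.

    Every target weight vector = r * source + sqrt(1 - r^2) * independent,
    so the hidden labelling rules correlate with coefficient `relatedness`
    (the analogue of how similar two assay targets are).  The source task
    does not depend on `relatedness`.
    """
    if relatedness is None:
        relatedness = spec.relatedness
    if not 0.0 <= relatedness <= 1.0:
        raise ValueError("relatedness must be in [0, 1]")
    source = make_task(spec)
    r = relatedness
    rc = np.sqrt(1 - r ** 2)
    ind = _hidden_weights(spec, stream=3)   # independent labelling rule
    w_target = HiddenWeights(
        w_local=r * source.weights.w_local + rc * ind.w_local,
        w_pos=r * source.weights.w_pos + rc * ind.w_pos,
        w_tok=r * source.weights.w_tok + rc * ind.w_tok,
    )
    t_spec = replace(spec, n=n_target, relatedness=r)
    rng = np.random.default_rng([spec.seed, 4])
    sequences = rng.integers(0, spec.vocab, size=(n_target, spec.seq_len))
    labels = _labels(sequences, w_target, t_spec,
                     np.random.default_rng([spec.seed, 5]))
    target = TokenTask(sequences=sequences, labels=labels, spec=t_spec,
                       weights=w_target)
    return source, target


def augment_token_task(task: TokenTask, n_extra: int = 9, seed: int = 0) -> TokenTask:
    """Permutation augmentation: each sequence plus `n_extra` random
    permutations, labels replicated.

    The sequence-world analogue of SMILES enumeration.  Only label-faithful
    for composition-driven (local) tasks, where a permutation provably
    preserves the label; training-set use only.
    """
    rng = np.random.default_rng(seed)
    n, L = task.sequences.shape
    out_seq = np.empty((n * (n_extra + 1), L), dtype=task.sequences.dtype)
    out_lab = np.repeat(task.labels, n_extra + 1)
    for i in range(n):
        base = task.sequences[i]
        out_seq[i * (n_extra + 1)] = base
        for j in range(n_extra):
            out_seq[i * (n_extra + 1) + 1 + j] = base[rng.permutation(L)]
    return TokenTask(sequences=out_seq, labels=out_lab, spec=task.spec,
                     weights=task.weights)
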
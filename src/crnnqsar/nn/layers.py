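"""Parameter containers and the recurrent / dense building blocks.

Models are plain objects holding a flat ``params`` dict (name -> Tensor), a
``groups`` dict assigning every parameter to exactly one named group
(``conv`` / ``gru`` / ``dense``) and a ``buffers`` dict for batch-norm
running statistics.  The freeze machinery in the training and transfer
modules operates purely on group names.
"""

from __future__ import annotations

import numpy as np

from . import autograd
from .autograd import Tensor, concat, relu, sigmoid, tanh

_ACTS = {"relu": relu, "tanh": tanh, "sigmoid": sigmoid}


def uniform_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class ParamStore:
    """Flat parameter/buffer registry shared by the CRNN and CNN models."""

    def __init__(self):
        self.params: dict[str, Tensor] = {}
        self.groups: dict[str, str] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def add_param(self, name: str, data: np.ndarray, group: str) -> Tensor:
        t = Tensor(data, requires_grad=True)
        self.params[name] = t
        self.groups[name] = group
        return t

    def add_buffer(self, name: str, data: np.ndarray) -> np.ndarray:
        data = np.asarray(data, dtype=autograd.DTYPE)
        self.buffers[name] = data
        return data

    def group_names(self) -> set:
        return set(self.groups.values())

    def param_count(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def group_param_count(self, group: str) -> int:
        return sum(p.data.size for n, p in self.params.items()
                   if self.groups[n] == group)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {f"param:{n}": p.data for n, p in self.params.items()}
        out.update({f"buffer:{n}": b for n, b in self.buffers.items()})
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for n, p in self.params.items():
            p.data = np.array(arrays[f"param:{n}"], dtype=autograd.DTYPE)
        for n in self.buffers:
            self.buffers[n] = np.array(arrays[f"buffer:{n}"], dtype=autograd.DTYPE)


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    return x @ w + b


def init_linear(store: ParamStore, rng: np.random.Generator, name: str,
                n_in: int, n_out: int, group: str) -> None:
    store.add_param(f"{name}.w", uniform_init(rng, (n_in, n_out), n_in), group)
    store.add_param(f"{name}.b", uniform_init(rng, (n_out,), n_in), group)


def init_gru(store: ParamStore, rng: np.random.Generator, name: str,
             n_in: int, hidden: int, bidirectional: bool) -> None:
    """Gated recurrent unit; gate order along the 3H axis is (update, reset, candidate)."""
    directions = ("fwd", "bwd") if bidirectional else ("fwd",)
    for d in directions:
        store.add_param(f"{name}.{d}.wx", uniform_init(rng, (n_in, 3 * hidden), n_in), "gru")
        store.add_param(f"{name}.{d}.wh", uniform_init(rng, (hidden, 3 * hidden), hidden), "gru")
        store.add_param(f"{name}.{d}.bx", uniform_init(rng, (3 * hidden,), n_in), "gru")
        store.add_param(f"{name}.{d}.bh", uniform_init(rng, (3 * hidden,), hidden), "gru")


def _np_sigmoid(a: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-a))


_NP_ACTS = {
    "relu": (lambda a: np.maximum(a, 0.0), lambda a, out: (a > 0).astype(float)),
    "tanh": (np.tanh, lambda a, out: 1.0 - out * out),
    "sigmoid": (_np_sigmoid, lambda a, out: out * (1.0 - out)),
}


def gru_direction(x: Tensor, wx: Tensor, wh: Tensor, bx: Tensor,
                  bh: Tensor, hidden: int, body_act: str,
                  reverse: bool, relu_gates: bool = False) -> Tensor:
    """Run one GRU direction over a (B, C, T) feature map; return final state.

    The input projections for all time steps run in a single matmul, and
    the whole time loop is one autodiff node: the recurrence and its
    backward pass (truncated-nothing BPTT) are hand-written numpy, which
    keeps per-step graph overhead out of the hot path.  The candidate
    ("body") activation is configurable; gates default to sigmoid, which
    preserves the convex-combination update of the hidden state.
    `relu_gates` swaps the gate nonlinearity too (provided for completeness;
    it abandons the gating semantics).
    """
    B, C, T = x.shape
    H = hidden
    # (B, C, T) -> (B*T, 3H) input projections for every step at once
    xp_all = x.transpose(0, 2, 1).reshape(B * T, C) @ wx + bx
    return _gru_loop(xp_all, wh, bh, B, T, H, body_act, reverse, relu_gates)


def _gru_loop(xp_all: Tensor, wh: Tensor, bh: Tensor, B: int, T: int, H: int,
              body_act: str, reverse: bool, relu_gates: bool) -> Tensor:
    """Fused GRU recurrence over precomputed input projections.

    Update per step: z, r = gate(xp + h @ wh + bh) for the update/reset
    slices; candidate n = body(xp_n + r * hp_n); h' = (1 - z) * n + z * h.
    """
    body_f, body_d = _NP_ACTS[body_act]
    gate_f, gate_d = _NP_ACTS["relu" if relu_gates else "sigmoid"]
    xp = xp_all.data.reshape(B, T, 3 * H)
    whd, bhd = wh.data, bh.data
    order = range(T - 1, -1, -1) if reverse else range(T)
    h = np.zeros((B, H), dtype=xp.dtype)
    cache = []
    for t in order:
        hp = h @ whd + bhd
        a_z = xp[:, t, 0:H] + hp[:, 0:H]
        a_r = xp[:, t, H:2 * H] + hp[:, H:2 * H]
        z = gate_f(a_z)
        r = gate_f(a_r)
        a_n = xp[:, t, 2 * H:] + r * hp[:, 2 * H:]
        n = body_f(a_n)
        h_new = (1.0 - z) * n + z * h
        cache.append((t, h, hp[:, 2 * H:], z, r, n,
                      gate_d(a_z, z), gate_d(a_r, r), body_d(a_n, n)))
        h = h_new
    out = Tensor(h, True, (xp_all, wh, bh))

    def bwd(g):
        dh = np.array(g)
        dxp = np.zeros((B, T, 3 * H), dtype=xp.dtype)
        dwh = np.zeros_like(whd)
        dbh = np.zeros_like(bhd)
        for (t, h_prev, hp_n, z, r, n, dz_a, dr_a, dn_a) in reversed(cache):
            dz = dh * (h_prev - n)
            dn = dh * (1.0 - z)
            da_n = dn * dn_a
            da_z = dz * dz_a
            da_r = da_n * hp_n * dr_a
            dxp[:, t, 0:H] = da_z
            dxp[:, t, H:2 * H] = da_r
            dxp[:, t, 2 * H:] = da_n
            dhp = np.concatenate([da_z, da_r, da_n * r], axis=1)
            dwh += h_prev.T @ dhp
            dbh += dhp.sum(axis=0)
            dh = dh * z + dhp @ whd.T
        if xp_all.requires_grad:
            xp_all._accumulate(dxp.reshape(B * T, 3 * H))
        if wh.requires_grad:
            wh._accumulate(dwh)
        if bh.requires_grad:
            bh._accumulate(dbh)
    out._backward = bwd
    return out


def bigru_summary(x: Tensor, store: ParamStore, name: str, hidden: int,
                  bidirectional: bool, body_act: str,
                  relu_gates: bool = False) -> Tensor:
    """Summarise a (B, C, T) feature map with a (bi)directional GRU.

    Returns the concatenated final hidden states of both directions,
    shape (B, 2*hidden) (or (B, hidden) if unidirectional).
    """
    p = store.params
    h_f = gru_direction(x, p[f"{name}.fwd.wx"], p[f"{name}.fwd.wh"],
                        p[f"{name}.fwd.bx"], p[f"{name}.fwd.bh"],
                        hidden, body_act, reverse=False, relu_gates=relu_gates)
    if not bidirectional:
        return h_f
    h_b = gru_direction(x, p[f"{name}.bwd.wx"], p[f"{name}.bwd.wh"],
                        p[f"{name}.bwd.bx"], p[f"{name}.bwd.bh"],
                        hidden, body_act, reverse=True, relu_gates=relu_gates)
    return concat([h_f, h_b], axis=1)
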
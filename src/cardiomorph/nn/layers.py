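"""Layer and module abstractions over the autograd core."""
from __future__ import annotations

import copy

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: recursive parameter collection and state dicts."""

    def parameters(self) -> list[Tensor]:
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(f"state has {len(state)} arrays, model has {len(params)}")
        for i, p in enumerate(params):
            p.data = state[f"p{i}"].astype(np.float32).copy()

    def copy_state(self) -> dict[str, np.ndarray]:
        return copy.deepcopy(self.state_dict())


def _param(array, name="") -> Tensor:
    return Tensor(array, requires_grad=True, name=name)


class Conv2d(Module):
    """3x3 (or kxk) stride-1 convolution with He initialization."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng=None, padding: str = "same"):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (c_in * k * k))
        self.w = _param(rng.normal(0, std, size=(c_out, c_in, k, k)), f"conv{c_in}->{c_out}")
        self.b = _param(np.zeros(c_out), "bias")
        self.padding = padding
        self.c_in, self.c_out, self.k = c_in, c_out, k

    def __call__(self, x):
        return ag.conv2d(x, self.w, self.b, padding=self.padding)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng=None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / n_in)
        self.w = _param(rng.normal(0, std, size=(n_in, n_out)), f"dense{n_in}->{n_out}")
        self.b = _param(np.zeros(n_out), "bias")

    def __call__(self, x):
        return ag.add(ag.matmul(x, self.w), self.b)


class TLU(Module):
    """Trainable linear unit: per-channel learnable slopes on both branches.

    ``f(x) = pos_slope * max(x, 0) + neg_slope * min(x, 0)``. Initialized at
    (1, 0.25): the positive branch starts as identity, the negative branch as
    a leaky rectifier; with neg_slope -> 0 the unit reduces to ReLU and with
    both slopes 1 to the identity.
    """

    def __init__(self, channels: int, pos_init: float = 1.0, neg_init: float = 0.25):
        shape = (1, channels, 1, 1)
        self.pos_slope = _param(np.full(shape, pos_init), "tlu_pos")
        self.neg_slope = _param(np.full(shape, neg_init), "tlu_neg")

    def __call__(self, x):
        pos = ag.relu(x)
        negpart = ag.sub(x, pos)  # min(x, 0)
        return ag.add(ag.mul(self.pos_slope, pos), ag.mul(self.neg_slope, negpart))


def tlu(x, pos_slope: float = 1.0, neg_slope: float = 0.0):
    """Functional TLU on plain arrays (the fixed-slope piecewise-linear map)."""
    x = np.asarray(x, dtype=float)
    return pos_slope * np.maximum(x, 0.0) + neg_slope * np.minimum(x, 0.0)


def instance_norm(x, eps: float = 1e-5):
    """Per-sample, per-channel normalization over spatial dims (NCHW)."""
    mu = ag.tmean(x, axis=(2, 3), keepdims=True)
    xc = ag.sub(x, mu)
    var = ag.tmean(ag.mul(xc, xc), axis=(2, 3), keepdims=True)
    return ag.mul(xc, ag.pow_const(ag.add(var, eps), -0.5))
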
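"""Neural-network building blocks on top of the autograd tensor.

Layers follow the usual conventions: channels-first convolution inputs
(``(N, C, D, H, W)`` for volumes, ``(N, C, T)`` for sequences), Glorot
initialisation for affine maps, and an explicit ``training`` flag that
gates dropout. Dropout layers own seedable generators so Monte-Carlo
passes can be replayed exactly.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, concatenate, stack

__all__ = [
    "Module", "Dense", "Dropout", "LayerNorm", "GatedResidual",
    "Conv3d", "Conv1d", "MaxPool3d", "MaxPool1d", "BiLSTM",
]


class Module:
    """Base class: parameter discovery, train/eval mode, dropout seeding."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for value in self.__dict__.values():
            if isinstance(value, Module):
                mods.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def seed_dropout(self, seed: int) -> None:
        """Reset every dropout generator deterministically from ``seed``."""
        for i, m in enumerate(m for m in self.modules() if isinstance(m, Dropout)):
            m.rng = np.random.default_rng((seed, i))

    def set_dropout_rate(self, rate: float) -> None:
        for m in self.modules():
            if isinstance(m, Dropout):
                m.rate = float(rate)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 activation: str | None = None):
        super().__init__()
        self.W = Tensor(_glorot(rng, (in_dim, out_dim)), requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)
        self.activation = activation

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.W + self.b
        if self.activation == "relu":
            y = y.relu()
        elif self.activation == "tanh":
            y = y.tanh()
        elif self.activation is not None:
            raise ValueError(f"unknown activation {self.activation!r}")
        return y


class Dropout(Module):
    """Inverted dropout; active in training mode (and hence during MC passes)."""

    def __init__(self, rate: float, seed: int = 0):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = float(rate)
        self.rng = np.random.default_rng(seed)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.data.shape) < keep) / keep
        return x * Tensor(mask)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gamma + self.beta


class GatedResidual(Module):
    """LayerNorm -> gated linear unit -> residual add.

    The gate is a learned sigmoid over the normalised features; the value
    path is the normalised features themselves, so a saturated gate
    (bias -> +inf) passes them through unchanged apart from the
    normalisation: ``y = x + sigmoid(W h + b) * h`` with ``h = LN(x)``.
    """

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.norm = LayerNorm(dim)
        self.gate = Dense(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.norm(x)
        return x + self.gate(h).sigmoid() * h


# -- convolution -------------------------------------------------------------


def _conv_nd_forward(x: np.ndarray, W: np.ndarray, stride: tuple[int, ...]):
    """im2col forward for N-d convolution, x: (N, C, *spatial)."""
    n_spatial = len(stride)
    kernel = W.shape[2:]
    axes = tuple(range(2, 2 + n_spatial))
    win = sliding_window_view(x, kernel, axis=axes)
    # win: (N, C, *out_full, *kernel); subsample by stride
    slicer = (slice(None), slice(None)) + tuple(slice(None, None, s) for s in stride)
    win = win[slicer]
    out_spatial = win.shape[2:2 + n_spatial]
    # (N, *out, C, *kernel)
    perm = (0,) + tuple(range(2, 2 + n_spatial)) + (1,) + \
        tuple(range(2 + n_spatial, win.ndim))
    cols = win.transpose(perm).reshape(-1, W.shape[1] * int(np.prod(kernel)))
    Wm = W.reshape(W.shape[0], -1).T  # (C*K, F)
    out = cols @ Wm
    out = out.reshape((x.shape[0],) + out_spatial + (W.shape[0],))
    # back to channels-first
    perm_out = (0, out.ndim - 1) + tuple(range(1, out.ndim - 1))
    return out.transpose(perm_out), cols, out_spatial


def _conv_nd_backward(g: np.ndarray, x_shape, W: np.ndarray, cols: np.ndarray,
                      out_spatial, stride):
    n_spatial = len(stride)
    kernel = W.shape[2:]
    F = W.shape[0]
    # g: (N, F, *out) -> (N*P, F)
    perm = (0,) + tuple(range(2, 2 + n_spatial)) + (1,)
    g2 = g.transpose(perm).reshape(-1, F)
    dW = (g2.T @ cols).reshape(W.shape)
    db = g2.sum(axis=0)
    dcols = g2 @ W.reshape(F, -1)  # (N*P, C*K)
    dx = np.zeros(x_shape)
    C = x_shape[1]
    dcols = dcols.reshape((x_shape[0],) + tuple(out_spatial) + (C,) + kernel)
    # scatter-add per kernel offset (small loop: prod(kernel) iterations)
    for offset in np.ndindex(*kernel):
        src = dcols[(slice(None),) * (1 + n_spatial) + (slice(None),) + offset]
        # src: (N, *out, C) -> (N, C, *out)
        src = np.moveaxis(src, -1, 1)
        dst = (slice(None), slice(None)) + tuple(
            slice(o, o + out_spatial[i] * stride[i], stride[i])
            for i, o in enumerate(offset))
        dx[dst] += src
    return dx, dW, db


class _ConvNd(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: tuple[int, ...],
                 stride: tuple[int, ...], rng: np.random.Generator):
        super().__init__()
        fan_in = in_ch * int(np.prod(kernel))
        limit = np.sqrt(6.0 / (fan_in + out_ch))
        self.W = Tensor(rng.uniform(-limit, limit, size=(out_ch, in_ch) + kernel),
                        requires_grad=True)
        self.b = Tensor(np.zeros(out_ch), requires_grad=True)
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        n_spatial = len(self.stride)
        if x.ndim != 2 + n_spatial:
            raise ValueError(f"expected {2 + n_spatial}-d input, got shape {x.shape}")
        for dim, k in zip(x.shape[2:], self.W.data.shape[2:]):
            if dim < k:
                raise ValueError(
                    f"input spatial size {x.shape[2:]} smaller than kernel "
                    f"{self.W.data.shape[2:]}")
        W, b, stride = self.W, self.b, self.stride
        out_data, cols, out_spatial = _conv_nd_forward(x.data, W.data, stride)
        bshape = (1, -1) + (1,) * n_spatial
        out_data = out_data + b.data.reshape(bshape)
        x_shape = x.data.shape

        def backward(g):
            dx, dW, db = _conv_nd_backward(g, x_shape, W.data, cols,
                                           out_spatial, stride)
            if x.requires_grad:
                x._accum(dx)
            W._accum(dW)
            b._accum(db)

        return Tensor._make(out_data, (x, W, b), backward)


class Conv3d(_ConvNd):
    def __init__(self, in_ch, out_ch, kernel: int | tuple, rng, stride=1):
        if isinstance(kernel, int):
            kernel = (kernel,) * 3
        if isinstance(stride, int):
            stride = (stride,) * 3
        super().__init__(in_ch, out_ch, tuple(kernel), tuple(stride), rng)


class Conv1d(_ConvNd):
    def __init__(self, in_ch, out_ch, kernel: int, rng, stride=1):
        super().__init__(in_ch, out_ch, (int(kernel),), (int(stride),), rng)


class _MaxPoolNd(Module):
    def __init__(self, factor: int, n_spatial: int):
        super().__init__()
        self.factor = int(factor)
        self.n_spatial = n_spatial

    def forward(self, x: Tensor) -> Tensor:
        f, nd = self.factor, self.n_spatial
        spatial = x.shape[2:]
        trimmed = tuple((s // f) * f for s in spatial)
        if any(t == 0 for t in trimmed):
            raise ValueError(f"input spatial size {spatial} too small for "
                             f"pool factor {f}")
        slicer = (slice(None), slice(None)) + tuple(slice(0, t) for t in trimmed)
        data = x.data[slicer]
        out_spatial = tuple(t // f for t in trimmed)
        # reshape each spatial axis into (out, f)
        new_shape = data.shape[:2]
        for o in out_spatial:
            new_shape += (o, f)
        blocks = data.reshape(new_shape)
        # move the f-axes to the end and flatten them
        f_axes = tuple(3 + 2 * i for i in range(nd))
        keep_axes = (0, 1) + tuple(2 + 2 * i for i in range(nd))
        blocks = blocks.transpose(keep_axes + f_axes)
        flat = blocks.reshape(blocks.shape[:2 + nd] + (f ** nd,))
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        x_shape = x.data.shape

        def backward(g):
            dflat = np.zeros_like(flat)
            np.put_along_axis(dflat, idx[..., None], g[..., None], axis=-1)
            dblocks = dflat.reshape(blocks.shape)
            inv = np.argsort(keep_axes + f_axes)
            dtrim = dblocks.transpose(inv).reshape(data.shape)
            dx = np.zeros(x_shape)
            dx[slicer] = dtrim
            x._accum(dx)

        return Tensor._make(out, (x,), backward)


class MaxPool3d(_MaxPoolNd):
    def __init__(self, factor: int = 2):
        super().__init__(factor, 3)


class MaxPool1d(_MaxPoolNd):
    def __init__(self, factor: int = 2):
        super().__init__(factor, 1)


# -- recurrent ---------------------------------------------------------------


class _LSTM(Module):
    """Single-direction LSTM; input (N, T, D) -> hidden sequence (N, T, H)."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        self.Wx = Tensor(_glorot(rng, (in_dim, 4 * hidden)), requires_grad=True)
        self.Wh = Tensor(_glorot(rng, (hidden, 4 * hidden)), requires_grad=True)
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        n, T, _ = x.shape
        H = self.hidden
        h = Tensor(np.zeros((n, H)))
        c = Tensor(np.zeros((n, H)))
        outs = []
        for t in range(T):
            xt = x[(slice(None), t, slice(None))]
            z = xt @ self.Wx + h @ self.Wh + self.b
            i = z[(slice(None), slice(0, H))].sigmoid()
            f = z[(slice(None), slice(H, 2 * H))].sigmoid()
            g = z[(slice(None), slice(2 * H, 3 * H))].tanh()
            o = z[(slice(None), slice(3 * H, 4 * H))].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs.append(h)
        return stack(outs, axis=1)


class BiLSTM(Module):
    """Bidirectional LSTM; per-token output dim is ``2 * hidden`` (fwd || bwd)."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = _LSTM(in_dim, hidden, rng)
        self.bwd = _LSTM(in_dim, hidden, rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 3 or x.shape[1] == 0:
            raise ValueError(f"expected non-empty (N, T, D) sequence, got {x.shape}")
        rev = x[(slice(None), slice(None, None, -1), slice(None))]
        h_f = self.fwd(x)
        h_b = self.bwd(rev)[(slice(None), slice(None, None, -1), slice(None))]
        return concatenate([h_f, h_b], axis=-1)
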
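"""Modality encoder branches.

* SNP: dense embedding of the scaled genotype features (an affine map
  ``Z_S = W_S S' + b_S``), chunked into fixed-width tokens and run
  through a bidirectional LSTM for a sequence-aware representation.
* MRI: per-patch 3-D convolutional stack; each patch becomes one token
  (channel features after spatial mean pooling).
* EEG: 1-D convolutional stack over the sequence of per-window band
  power-spectral-density feature vectors (the default input path), or
  over raw filtered samples.

Every branch ends in a linear projection to the shared fusion
dimension, so all three token sets are directly comparable in the
attention block.
"""

from __future__ import annotations

import numpy as np

from .config import ModelConfig
from .nn import (Tensor, as_tensor, BiLSTM, Conv1d, Conv3d, Dense, Dropout,
                 MaxPool3d, Module)

__all__ = ["embed_snp", "SnpEncoder", "VolumeEncoder", "TimeseriesEncoder"]


def _pad_spatial(h, kernel):
    """Zero-pad trailing spatial axes of (N, C, *spatial) up to ``kernel``."""
    from .nn import concatenate
    for axis, k in enumerate(kernel):
        dim = h.shape[2 + axis]
        if dim < k:
            pad_shape = list(h.shape)
            pad_shape[2 + axis] = k - dim
            h = concatenate([h, Tensor(np.zeros(pad_shape))], axis=2 + axis)
    return h


def embed_snp(S: np.ndarray, W_S: np.ndarray, b_S: np.ndarray) -> np.ndarray:
    """Dense SNP embedding ``Z_S = W_S S' + b_S`` with ``W_S`` of shape (m, p).

    Accepts a single feature row (p,) or a stack (n, p); returns (m,) or
    (n, m) correspondingly.
    """
    S = np.asarray(S, dtype=float)
    W_S = np.asarray(W_S, dtype=float)
    b_S = np.asarray(b_S, dtype=float)
    p = W_S.shape[1]
    if S.shape[-1] != p:
        raise ValueError(f"expected {p} SNP features, got {S.shape[-1]}")
    return S @ W_S.T + b_S


class SnpEncoder(Module):
    """Embedding -> token chunking -> Bi-LSTM -> projected tokens."""

    def __init__(self, in_dim: int, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        m, w = cfg.snp_embed_dim, cfg.snp_token_width
        if m % w != 0:
            raise ValueError(f"snp_embed_dim {m} must be divisible by "
                             f"snp_token_width {w}")
        self.n_tokens = m // w
        self.token_width = w
        self.embed = Dense(in_dim, m, rng)
        self.lstm = BiLSTM(w, cfg.lstm_hidden, rng)
        self.dropout = Dropout(cfg.dropout)
        self.project = Dense(2 * cfg.lstm_hidden, cfg.fusion_dim, rng)

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        z = self.embed(x)                                   # (N, m)
        tokens = z.reshape(z.shape[0], self.n_tokens, self.token_width)
        h = self.lstm(tokens)                               # (N, t, 2H)
        h = self.dropout(h)
        return self.project(h)                              # (N, t, d)


class VolumeEncoder(Module):
    """Stacked 3-D convolution blocks applied per patch; token per patch."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.convs: list[Module] = []
        in_ch = 1
        for i, f in enumerate(cfg.cnn_filters):
            stride = cfg.cnn_first_stride if i == 0 else 1
            self.convs.append(Conv3d(in_ch, f, cfg.cnn_kernel, rng,
                                     stride=stride))
            in_ch = f
        self.pool = MaxPool3d(2)
        self.dropout = Dropout(cfg.dropout)
        self.project = Dense(in_ch, cfg.fusion_dim, rng)

    def forward(self, x) -> Tensor:
        """x: (N, n_patch, ph, pw, pd) -> tokens (N, n_patch, fusion_dim)."""
        x = as_tensor(x)
        n, n_patch = x.shape[0], x.shape[1]
        h = x.reshape(n * n_patch, 1, *x.shape[2:])
        for i, conv in enumerate(self.convs):
            if i > 0:   # deeper layers pad; undersized inputs still error
                h = _pad_spatial(h, conv.W.shape[2:])
            h = conv(h).relu()
            if min(h.shape[2:]) >= 2:
                h = self.pool(h)
        h = h.reshape(*h.shape[:2], -1).mean(axis=2)        # (N*P, C)
        h = self.dropout(h)
        tokens = self.project(h).reshape(n, n_patch, -1)
        return tokens


class TimeseriesEncoder(Module):
    """Stacked 1-D convolutions over a (N, T, features) sequence."""

    def __init__(self, in_features: int, cfg: ModelConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.convs: list[Module] = []
        in_ch = in_features
        for f in cfg.cnn_filters:
            self.convs.append(Conv1d(in_ch, f, min(cfg.cnn_kernel, 3), rng))
            in_ch = f
        self.dropout = Dropout(cfg.dropout)
        self.project = Dense(in_ch, cfg.fusion_dim, rng)

    def forward(self, x) -> Tensor:
        """x: (N, T, features) -> tokens (N, T', fusion_dim)."""
        x = as_tensor(x)
        h = x.swapaxes(1, 2)                                # (N, C, T)
        for conv in self.convs:
            k = conv.W.shape[2]
            if h.shape[2] < k:  # zero-pad short sequences up to the kernel
                from .nn import concatenate, Tensor
                pad = Tensor(np.zeros((h.shape[0], h.shape[1],
                                       k - h.shape[2])))
                h = concatenate([h, pad], axis=2)
            h = conv(h).relu()
        h = h.swapaxes(1, 2)                                # (N, T', C)
        h = self.dropout(h)
        return self.project(h)
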
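"""Self-attention, cross-modality attention and the fusion head.

Attention follows the scaled-dot-product form: per-modality queries,
keys and values are linear (bias-free) projections of the token set,
attention weights are the row-softmax of ``Q K^T / sqrt(d_k)``, and
outputs are the weight-averaged values. Cross-modality attention runs
in exactly three directions — SNP queries attending to MRI keys/values
(``C_SM``), SNP to EEG (``C_SE``), MRI to EEG (``C_ME``) — and the
self- and cross-attended outputs are combined additively per modality:

    F_S  = O_S + C_SM + C_SE
    F_M' = O_M + C_SM + C_ME
    F_E' = O_E + C_SE + C_ME

Because each cross output has its querying modality's token count, all
attended outputs are mean-pooled over their token axis and projected to
the shared fusion dimension before the sums (the only reading under
which the combination is well-typed); the same pooled ``C_SM`` enters
both ``F_S`` and ``F_M'``. Terms involving an absent modality
contribute zero. The fused vectors are concatenated, passed through a
dense layer with dropout, and refined by a LayerNorm -> gated linear
unit -> residual block before the class logits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelConfig
from .nn import (Tensor, as_tensor, concatenate, Dense, Dropout,
                 GatedResidual, Module)

__all__ = [
    "AttentionParams", "scaled_dot_attention", "self_attention",
    "cross_attention", "fuse_modalities", "AttentionFusion", "FusionHead",
]


@dataclass
class AttentionParams:
    """Projection matrices for one modality's queries/keys/values."""
    Wq: np.ndarray   # (d_in, d_k)
    Wk: np.ndarray   # (d_in, d_k)
    Wv: np.ndarray   # (d_in, d_v)

    @property
    def d_k(self) -> int:
        return self.Wq.shape[1]

    def __post_init__(self):
        if self.Wq.shape[1] != self.Wk.shape[1]:
            raise ValueError(
                f"query/key dimension mismatch: {self.Wq.shape[1]} vs "
                f"{self.Wk.shape[1]}")


def scaled_dot_attention(Q: Tensor, K: Tensor, V: Tensor,
                         d_k: int) -> tuple[Tensor, Tensor]:
    """``A = softmax(Q K^T / sqrt(d_k))``, ``O = A V`` (batched)."""
    Q, K, V = as_tensor(Q), as_tensor(K), as_tensor(V)
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError(f"query dim {Q.shape[-1]} != key dim {K.shape[-1]}")
    if K.shape[-2] == 0:
        raise ValueError("attention requires at least one key token")
    logits = (Q @ K.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k))
    A = logits.softmax(axis=-1)
    return A, A @ V


def self_attention(tokens: np.ndarray, params: AttentionParams):
    """Within-modality attention. Returns ``(A, O)`` as arrays."""
    tokens = np.asarray(tokens, dtype=float)
    if tokens.shape[-2] < 1:
        raise ValueError("need at least one token")
    Q = Tensor(tokens @ params.Wq)
    K = Tensor(tokens @ params.Wk)
    V = Tensor(tokens @ params.Wv)
    A, O = scaled_dot_attention(Q, K, V, params.d_k)
    return A.data, O.data


def cross_attention(query_tokens: np.ndarray, key_value_tokens: np.ndarray,
                    query_params: AttentionParams,
                    kv_params: AttentionParams) -> np.ndarray:
    """One modality's queries attending to another's keys/values."""
    query_tokens = np.asarray(query_tokens, dtype=float)
    key_value_tokens = np.asarray(key_value_tokens, dtype=float)
    if key_value_tokens.shape[-2] == 0:
        raise ValueError("empty key/value token set (softmax undefined)")
    Q = Tensor(query_tokens @ query_params.Wq)
    K = Tensor(key_value_tokens @ kv_params.Wk)
    V = Tensor(key_value_tokens @ kv_params.Wv)
    _, C = scaled_dot_attention(Q, K, V, query_params.d_k)
    return C.data


def fuse_modalities(O_S, O_M, O_E, C_SM, C_SE, C_ME,
                    mask=(True, True, True)):
    """Combine pooled self- and cross-attended outputs per modality.

    All inputs are pooled vectors (or batches of them) in the shared
    fusion dimension. A term is dropped (contributes zero) when any
    modality it involves is masked out; masked sums are not rescaled, so
    zeroing a modality's contributions and masking it coincide.
    Returns ``(F_S, F_M', F_E')``.
    """
    O_S, O_M, O_E = (np.asarray(x, dtype=float) for x in (O_S, O_M, O_E))
    C_SM, C_SE, C_ME = (np.asarray(x, dtype=float)
                        for x in (C_SM, C_SE, C_ME))
    shapes = {x.shape for x in (O_S, O_M, O_E, C_SM, C_SE, C_ME)}
    if len(shapes) != 1:
        raise ValueError(f"fusion inputs disagree in shape: {sorted(shapes)}")
    m_s, m_m, m_e = (float(bool(b)) for b in mask)
    F_S = m_s * (O_S + m_m * C_SM + m_e * C_SE)
    F_M = m_m * (O_M + m_s * C_SM + m_e * C_ME)
    F_E = m_e * (O_E + m_s * C_SE + m_m * C_ME)
    return F_S, F_M, F_E


class _QKV(Module):
    """Bias-free query/key/value projections for one modality.

    Values start at the identity so attended outputs begin as plain
    token (mixtures) rather than random projections; queries and keys
    are Glorot-initialised.
    """

    def __init__(self, dim: int, d_k: int, rng: np.random.Generator):
        super().__init__()
        lim = np.sqrt(6.0 / (dim + d_k))
        self.Wq = Tensor(rng.uniform(-lim, lim, (dim, d_k)), requires_grad=True)
        self.Wk = Tensor(rng.uniform(-lim, lim, (dim, d_k)), requires_grad=True)
        self.Wv = Tensor(np.eye(dim), requires_grad=True)


class AttentionFusion(Module):
    """Batched self- + cross-attention producing pooled fused vectors."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        d = cfg.fusion_dim
        self.d_k = cfg.d_k
        self.qkv_s = _QKV(d, cfg.d_k, rng)
        self.qkv_m = _QKV(d, cfg.d_k, rng)
        self.qkv_e = _QKV(d, cfg.d_k, rng)
        # pooled-output projections into the shared fusion dimension;
        # residual-style initialisation: self terms start at the identity
        # and cross terms at zero, so the fused vectors begin as clean
        # per-modality features and cross-attention grows in as learned
        self.proj = {name: Dense(d, d, rng) for name in
                     ("O_S", "O_M", "O_E", "C_SM", "C_SE", "C_ME")}
        for name, dense in self.proj.items():
            if name.startswith("O_"):
                dense.W.data = np.eye(d)
            else:
                dense.W.data[:] = 0.0
        self._proj_modules = list(self.proj.values())  # parameter discovery

    def _pool(self, name: str, tokens: Tensor) -> Tensor:
        return self.proj[name](tokens.mean(axis=1))

    def forward(self, tok_s: Tensor, tok_m: Tensor, tok_e: Tensor,
                mask: np.ndarray):
        """Token sets (N, t_X, d) and mask (N, 3) -> fused (N, d) triple."""
        qs, ks, vs = (tok_s @ self.qkv_s.Wq, tok_s @ self.qkv_s.Wk,
                      tok_s @ self.qkv_s.Wv)
        qm, km, vm = (tok_m @ self.qkv_m.Wq, tok_m @ self.qkv_m.Wk,
                      tok_m @ self.qkv_m.Wv)
        qe, ke, ve = (tok_e @ self.qkv_e.Wq, tok_e @ self.qkv_e.Wk,
                      tok_e @ self.qkv_e.Wv)
        _, o_s = scaled_dot_attention(qs, ks, vs, self.d_k)
        _, o_m = scaled_dot_attention(qm, km, vm, self.d_k)
        _, o_e = scaled_dot_attention(qe, ke, ve, self.d_k)
        _, c_sm = scaled_dot_attention(qs, km, vm, self.d_k)
        _, c_se = scaled_dot_attention(qs, ke, ve, self.d_k)
        _, c_me = scaled_dot_attention(qm, ke, ve, self.d_k)

        O_S = self._pool("O_S", o_s)
        O_M = self._pool("O_M", o_m)
        O_E = self._pool("O_E", o_e)
        C_SM = self._pool("C_SM", c_sm)
        C_SE = self._pool("C_SE", c_se)
        C_ME = self._pool("C_ME", c_me)

        mask = np.asarray(mask, dtype=float)
        m_s = Tensor(mask[:, 0:1])
        m_m = Tensor(mask[:, 1:2])
        m_e = Tensor(mask[:, 2:3])
        F_S = m_s * (O_S + m_m * C_SM + m_e * C_SE)
        F_M = m_m * (O_M + m_s * C_SM + m_e * C_ME)
        F_E = m_e * (O_E + m_s * C_SE + m_m * C_ME)
        return F_S, F_M, F_E


class FusionHead(Module):
    """Concatenation -> dense -> dropout -> LayerNorm/GLU/residual -> logits."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 n_classes: int = 3):
        super().__init__()
        if not 0.0 <= cfg.dropout < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {cfg.dropout}")
        self.dense = Dense(3 * cfg.fusion_dim, cfg.fc_units, rng)
        self.dropout = Dropout(cfg.dropout)
        self.refine = GatedResidual(cfg.fc_units, rng)
        self.classify = Dense(cfg.fc_units, n_classes, rng)

    def forward(self, F_S: Tensor, F_M: Tensor, F_E: Tensor):
        """Returns ``(Z_drop, logits)``."""
        f_concat = concatenate([F_S, F_M, F_E], axis=-1)
        z = self.dense(f_concat)
        z_drop = self.dropout(z)
        refined = self.refine(z_drop)
        return z_drop, self.classify(refined)
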
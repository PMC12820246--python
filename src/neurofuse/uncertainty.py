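"""Monte-Carlo-dropout uncertainty and the composite training objective.

MC dropout keeps dropout active at inference and draws ``T`` stochastic
forward passes; the predictive mean and per-class variance are

    mu      = (1/T) sum_t y_t
    sigma^2 = (1/T) sum_t (y_t - mu)^2        (population variance)

Epistemic uncertainty is the class-mean of sigma^2. Aleatoric
uncertainty — noise the model attributes to the data itself — has no
closed form prescribed here, so the standard decomposition partner is
used: the mean over passes of the per-pass predictive variance
``sum_c y_tc (1 - y_tc)``. Total uncertainty is their sum,
``U_final = epistemic + aleatoric``, which makes the additive identity
exact by construction.

The composite objective is

    L_final = L_CE + U + lambda * ||W||_2^2 + alpha * |W|_1 + D_KL + L_focal

with cross-entropy on the MC-averaged calibrated softmax, the batch-mean
total uncertainty from a small number of in-graph stochastic passes
(differentiable, unlike the 30-pass inference estimate), an L2 and an L1
weight penalty, a MC-dropout variational KL surrogate (a dropout-scaled
squared-weight penalty, always >= 0), and a focal term
``-w_c (1 - p_c)^gamma log p_c`` against class imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .config import LossConfig, MCConfig
from .nn import Module, Tensor, stack

__all__ = [
    "UncertaintyEstimate", "LossTerms", "mc_predict", "decompose_uncertainty",
    "calibrated_softmax", "fit_temperature", "cross_entropy", "focal_loss",
    "total_loss",
]

_EPS = 1e-12


@dataclass
class UncertaintyEstimate:
    samples: np.ndarray      # (T, n, C) per-pass class probabilities
    mean: np.ndarray         # (n, C) predictive mean mu
    variance: np.ndarray     # (n, C) per-class epistemic variance sigma^2
    epistemic: np.ndarray    # (n,) class-mean of sigma^2
    aleatoric: np.ndarray    # (n,)
    total: np.ndarray        # (n,) U_final = epistemic + aleatoric


def _check_probabilities(samples: np.ndarray) -> None:
    if samples.min() < -1e-9 or samples.max() > 1 + 1e-9:
        raise ValueError("sample vectors must be probabilities in [0, 1]")
    sums = samples.sum(axis=-1)
    if np.abs(sums - 1).max() > 1e-6:
        raise ValueError("sample vectors must sum to 1")


def _population_var(samples: np.ndarray, mu: np.ndarray) -> np.ndarray:
    var = ((samples - mu) ** 2).mean(axis=0)
    # identical passes must give exactly zero (guard against the 1-ulp
    # error of the mean of bit-identical floats)
    var[np.ptp(samples, axis=0) == 0] = 0.0
    return var


def decompose_uncertainty(samples) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split MC samples into (epistemic, aleatoric, total) per subject.

    ``samples`` is (T, C) for one subject or (T, n, C) for a batch.
    """
    samples = np.asarray(samples, dtype=float)
    single = samples.ndim == 2
    if single:
        samples = samples[:, None, :]
    if samples.ndim != 3 or samples.shape[0] < 1:
        raise ValueError("samples must be (T, n, C) with T >= 1")
    _check_probabilities(samples)
    mu = samples.mean(axis=0)
    var = _population_var(samples, mu)             # divisor T (population)
    epistemic = var.mean(axis=-1)
    aleatoric = (samples * (1 - samples)).sum(axis=-1).mean(axis=0)
    total = epistemic + aleatoric
    if single:
        return epistemic[0], aleatoric[0], total[0]
    return epistemic, aleatoric, total


def mc_predict(model: Module, batch: dict, mc: MCConfig,
               temperature: float = 1.0) -> UncertaintyEstimate:
    """Monte-Carlo-dropout predictive posterior for a feature batch.

    Runs ``mc.num_passes`` stochastic forward passes with dropout active,
    each seeded from ``mc.seed`` plus the pass index so runs replay
    exactly. The model is returned in evaluation mode.
    """
    if mc.num_passes < 1:
        raise ValueError("num_passes must be >= 1")
    model.train()  # dropout active
    passes = []
    for t in range(mc.num_passes):
        model.seed_dropout(mc.seed + t)
        logits = model(batch)
        passes.append(calibrated_softmax(logits.data, temperature))
    model.eval()
    samples = np.stack(passes)                      # (T, n, C)
    mu = samples.mean(axis=0)
    var = _population_var(samples, mu)
    epistemic, aleatoric, total = decompose_uncertainty(samples)
    return UncertaintyEstimate(samples=samples, mean=mu, variance=var,
                               epistemic=epistemic, aleatoric=aleatoric,
                               total=total)


def calibrated_softmax(logits, temperature: float = 1.0) -> np.ndarray:
    """Temperature-scaled softmax, ``softmax(logits / temperature)``."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    z = np.asarray(logits, dtype=float) / temperature
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _nll(logits: np.ndarray, labels: np.ndarray, temperature: float) -> float:
    p = calibrated_softmax(logits, temperature)
    return float(-np.mean(np.log(
        np.clip(p[np.arange(len(labels)), labels], _EPS, None))))


def fit_temperature(logits: np.ndarray, labels: np.ndarray) -> float:
    """Temperature minimising validation NLL (1-D search on log T).

    Guaranteed not to increase the NLL relative to temperature 1.
    """
    logits = np.asarray(logits, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("temperature fitting needs >= 2 classes represented")
    res = minimize_scalar(lambda u: _nll(logits, labels, float(np.exp(u))),
                          bounds=(np.log(0.05), np.log(50.0)),
                          method="bounded")
    t_hat = float(np.exp(res.x))
    return t_hat if _nll(logits, labels, t_hat) <= _nll(logits, labels, 1.0) \
        else 1.0


def _as_one_hot(y, n_classes: int) -> np.ndarray:
    y = np.asarray(y)
    if y.ndim == 0:
        y = y[None]
        out = np.zeros((1, n_classes))
        out[0, int(y[0])] = 1.0
        return out[0]
    if y.ndim == 1 or (y.ndim == 2 and y.shape[-1] != n_classes):
        out = np.zeros(y.shape + (n_classes,))
        np.put_along_axis(out, y[..., None], 1.0, axis=-1)
        return out
    bad = ~(np.isin(y, (0, 1)).all() and (y.sum(axis=-1) == 1).all())
    if bad:
        raise ValueError("y must be one-hot")
    return y.astype(float)


def cross_entropy(y_hat, y) -> float:
    """``-sum_i y_i log y_hat_i`` with probabilities clipped to [eps, 1-eps]."""
    y_hat = np.asarray(y_hat, dtype=float)
    y = _as_one_hot(y, y_hat.shape[-1])
    p = np.clip(y_hat, _EPS, 1 - _EPS)
    ce = -(y * np.log(p)).sum(axis=-1)
    return float(ce.mean()) if ce.ndim else float(ce)


def focal_loss(y_hat, y, gamma: float = 2.0, class_weights=None) -> float:
    """Focal loss ``-w_c (1 - p_c)^gamma log p_c`` on the true class c.

    With ``gamma=0`` and unit weights this reduces exactly to the
    cross-entropy.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    y_hat = np.asarray(y_hat, dtype=float)
    n_classes = y_hat.shape[-1]
    y = _as_one_hot(y, n_classes)
    if class_weights is None:
        class_weights = np.ones(n_classes)
    w = np.asarray(class_weights, dtype=float)
    p = np.clip(y_hat, _EPS, 1 - _EPS)
    p_true = (y * p).sum(axis=-1)
    w_true = (y * w).sum(axis=-1)
    loss = -w_true * (1 - p_true) ** gamma * np.log(p_true)
    return float(loss.mean()) if loss.ndim else float(loss)


@dataclass
class LossTerms:
    ce: float
    uncertainty: float
    l2: float
    l1: float
    kl: float
    focal: float
    total: float
    graph: Tensor | None = None   # differentiable L_final

    def as_dict(self) -> dict[str, float]:
        return {"ce": self.ce, "uncertainty": self.uncertainty,
                "l2": self.l2, "l1": self.l1, "kl": self.kl,
                "focal": self.focal, "total": self.total}


def total_loss(model: Module, batch: dict, labels: np.ndarray,
               loss_cfg: LossConfig, mc: MCConfig,
               class_weights=None, pass_seed: int = 0,
               temperature: float = 1.0) -> LossTerms:
    """Differentiable composite objective on one batch.

    Runs ``mc.training_passes`` stochastic passes inside the graph; the
    MC-averaged calibrated softmax feeds the cross-entropy and focal
    terms, and the per-sample total uncertainty of the same passes forms
    the (batch-mean) uncertainty term. With all dropout rates 0 the
    passes coincide, the uncertainty term's epistemic part is exactly 0,
    and with zero coefficients ``L_final == L_CE``.
    """
    for name in ("lam", "alpha", "kl_coeff", "gamma", "uncertainty_weight",
                 "focal_weight"):
        if getattr(loss_cfg, name) < 0:
            raise ValueError(f"loss coefficient {name} must be >= 0")
    labels = np.asarray(labels, dtype=int)
    n_classes = 3
    y = _as_one_hot(labels, n_classes)
    if class_weights is None:
        class_weights = np.ones(n_classes)
    w_true = Tensor((y * np.asarray(class_weights)).sum(axis=-1))

    was_training = model.training
    model.train()
    passes = []
    for t in range(max(1, mc.training_passes)):
        model.seed_dropout(pass_seed * 1000003 + t)
        logits = model(batch)
        probs = (logits * (1.0 / temperature)).softmax(axis=-1)
        passes.append(probs)
    model.train(was_training)

    P = stack(passes, axis=0)                       # (T, n, C)
    mu = P.mean(axis=0)                             # (n, C)
    var = ((P - mu) ** 2).mean(axis=0)              # (n, C)
    epistemic = var.mean(axis=-1)                   # (n,)
    aleatoric = (P * (1.0 - P)).sum(axis=-1).mean(axis=0)
    u_final = epistemic + aleatoric                 # (n,)

    p_clip = mu.clip(_EPS, 1 - _EPS)
    y_t = Tensor(y)
    ce = -(y_t * p_clip.log()).sum(axis=-1).mean()
    p_true = (y_t * p_clip).sum(axis=-1)
    focal = (w_true * (1.0 - p_true) ** loss_cfg.gamma
             * -(p_true.log())).mean() * loss_cfg.focal_weight

    params = model.parameters()
    l2 = None
    l1 = None
    for p in params:
        sq = (p * p).sum()
        ab = p.abs().sum()
        l2 = sq if l2 is None else l2 + sq
        l1 = ab if l1 is None else l1 + ab
    # MC-dropout variational KL surrogate: dropout-scaled squared weights
    drop_rate = max((m.rate for m in model.modules()
                     if hasattr(m, "rate")), default=0.0)
    kl = l2 * (loss_cfg.kl_coeff * (1.0 - drop_rate) / 2.0)

    u_term = u_final.mean() * loss_cfg.uncertainty_weight
    l2_term = l2 * loss_cfg.lam
    l1_term = l1 * loss_cfg.alpha
    final = ce + u_term + l2_term + l1_term + kl + focal

    return LossTerms(
        ce=float(ce.data), uncertainty=float(u_term.data),
        l2=float(l2_term.data), l1=float(l1_term.data), kl=float(kl.data),
        focal=float(focal.data), total=float(final.data), graph=final)
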
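"""The tri-modal classifier: encoder branches + fusion + head.

The model consumes per-sample preprocessed features:

* ``snp``  — (N, p') scaled genotype features (post PCA),
* ``mri``  — (N, n_patch, ph, pw, pd) normalised volume patches,
* ``eeg``  — (N, T, f) per-window band-PSD feature sequences,
* ``mask`` — (N, 3) modality availability (SNP, MRI, EEG).

With ``attention=True`` the encoder token sets go through the
self-/cross-attention fusion block; with ``attention=False`` the
pooled encoder outputs are concatenated directly (the no-attention
ablation), masked the same way. Either path ends in the shared fusion
head. Restricting ``modalities`` simply forces the mask columns of the
excluded modalities to zero and skips building their encoders.
"""

from __future__ import annotations

import numpy as np

from .config import ModelConfig
from .encoders import SnpEncoder, TimeseriesEncoder, VolumeEncoder
from .fusion import AttentionFusion, FusionHead
from .nn import Tensor, as_tensor, Module

__all__ = ["TriModalClassifier", "MODALITIES"]

MODALITIES = ("snp", "mri", "eeg")


class TriModalClassifier(Module):
    def __init__(self, snp_dim: int, eeg_features: int,
                 cfg: ModelConfig | None = None,
                 modalities: tuple[str, ...] = MODALITIES,
                 attention: bool = True, seed: int = 0):
        super().__init__()
        if not modalities:
            raise ValueError("at least one modality is required")
        unknown = set(modalities) - set(MODALITIES)
        if unknown:
            raise ValueError(f"unknown modalities {sorted(unknown)}")
        self.cfg = cfg = cfg or ModelConfig()
        self.modalities = tuple(m for m in MODALITIES if m in modalities)
        self.attention = attention
        rng = np.random.default_rng(seed)
        d = cfg.fusion_dim
        self.snp_encoder = (SnpEncoder(snp_dim, cfg, rng)
                            if "snp" in modalities else None)
        self.mri_encoder = (VolumeEncoder(cfg, rng)
                            if "mri" in modalities else None)
        self.eeg_encoder = (TimeseriesEncoder(eeg_features, cfg, rng)
                            if "eeg" in modalities else None)
        self.fusion = AttentionFusion(cfg, rng) if attention else None
        self.head = FusionHead(cfg, rng)
        self._d = d
        self._snp_dim = snp_dim
        self._eeg_features = eeg_features
        self.seed_dropout(seed)

    def _effective_mask(self, mask: np.ndarray, n: int) -> np.ndarray:
        mask = (np.ones((n, 3)) if mask is None
                else np.asarray(mask, dtype=float).reshape(n, 3).copy())
        for i, m in enumerate(MODALITIES):
            if m not in self.modalities:
                mask[:, i] = 0.0
        if not mask.any(axis=1).all():
            raise ValueError("every sample needs at least one live modality")
        return mask

    def forward(self, batch: dict, return_tokens: bool = False):
        """Compute class logits for a feature batch. Returns a Tensor
        (N, 3), or ``(logits, token_dict)`` with ``return_tokens``."""
        n = next(
            (batch[m].shape if hasattr(batch[m], "shape")
             else np.asarray(batch[m]).shape)[0]
            for m in self.modalities if m in batch)
        mask = self._effective_mask(batch.get("mask"), n)
        zeros = Tensor(np.zeros((n, 1, self._d)))
        tok_s = (self.snp_encoder(as_tensor(batch["snp"]))
                 if self.snp_encoder is not None else zeros)
        tok_m = (self.mri_encoder(as_tensor(batch["mri"]))
                 if self.mri_encoder is not None else zeros)
        tok_e = (self.eeg_encoder(as_tensor(batch["eeg"]))
                 if self.eeg_encoder is not None else zeros)

        if self.attention:
            F_S, F_M, F_E = self.fusion(tok_s, tok_m, tok_e, mask)
        else:
            # plain concatenation ablation: masked pooled encoder outputs
            m = np.asarray(mask, dtype=float)
            F_S = tok_s.mean(axis=1) * Tensor(m[:, 0:1])
            F_M = tok_m.mean(axis=1) * Tensor(m[:, 1:2])
            F_E = tok_e.mean(axis=1) * Tensor(m[:, 2:3])
        _, logits = self.head(F_S, F_M, F_E)
        if return_tokens:
            return logits, {"snp": tok_s, "mri": tok_m, "eeg": tok_e}
        return logits

    def save(self, path: str) -> None:
        """Serialise weights + architecture metadata to an .npz file."""
        import json
        from dataclasses import asdict
        meta = {"cfg": asdict(self.cfg), "modalities": list(self.modalities),
                "attention": self.attention, "snp_dim": self._snp_dim,
                "eeg_features": self._eeg_features}
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str) -> "TriModalClassifier":
        import json
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            cfg = ModelConfig(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in meta["cfg"].items()})
            model = cls(snp_dim=meta["snp_dim"],
                        eeg_features=meta["eeg_features"], cfg=cfg,
                        modalities=tuple(meta["modalities"]),
                        attention=meta["attention"])
            for i, p in enumerate(model.parameters()):
                p.data = data[f"p{i}"]
        model.eval()
        return model

    def describe(self) -> str:
        cfg = self.cfg
        lines = [
            f"modalities: {'+'.join(self.modalities)}",
            f"fusion: {'cross-modality attention' if self.attention else 'concatenation'}",
            f"fusion_dim={cfg.fusion_dim} d_k={cfg.d_k}",
        ]
        if self.snp_encoder is not None:
            lines.append(
                f"snp: dense->{cfg.snp_embed_dim}, tokens of {cfg.snp_token_width}, "
                f"BiLSTM({cfg.lstm_hidden}) -> {2 * cfg.lstm_hidden}/token")
        if self.mri_encoder is not None:
            lines.append(f"mri: Conv3d filters {cfg.cnn_filters}, "
                         f"kernel {cfg.cnn_kernel}, maxpool 2")
        if self.eeg_encoder is not None:
            lines.append(f"eeg: Conv1d filters {cfg.cnn_filters}")
        lines.append(f"head: dense({cfg.fc_units}) -> dropout({cfg.dropout}) "
                     f"-> LayerNorm/GLU/residual -> 3 classes")
        lines.append(f"parameters: {self.n_parameters()}")
        return "\n".join(lines)
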
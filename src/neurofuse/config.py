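"""Experiment configuration: model, preprocessing, loss and tuning schedule.

Two schedule presets are provided. ``reference_schedule`` is the full
ten-stage progressive tuning run (learning rate annealed 1e-3 -> 1e-5,
batch size 32 -> 16, dropout 0.5 -> 0.2, epochs 10 -> 50, convolution
kernels widened 3 -> 5 and capacity grown 64 -> 256 filters /
128 -> 256 LSTM units across stages). ``desk_schedule`` is a three-stage
compression of the same annealing pattern sized for quick CPU runs and
is the default. Because weights are carried across stages, the realised
architecture is fixed by :class:`ModelConfig`; the per-stage capacity
columns of the reference schedule are kept as stage metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

BANDS = ("delta", "theta", "alpha", "beta")
#: Band edges in Hz, half-open intervals [lo, hi).
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

CLASSES = ("AD", "PD", "HC")


@dataclass
class PreprocessConfig:
    clip_threshold: float = 3.0          # z-score truncation, in SDs
    pca_variance_target: float = 0.95    # cumulative explained variance
    pca_max_components: int = 200        # hard cap applied after the variance rule
    bandpass_low: float = 0.5            # Hz
    bandpass_high: float = 40.0          # Hz
    filter_order: int = 4                # zero-phase Butterworth
    welch_window_s: float = 2.0          # Hann window length, seconds
    welch_overlap: float = 0.5
    eeg_window_s: float = 2.0            # per-recording feature windows (tokens)
    patch_size: tuple[int, int, int] = (64, 64, 64)
    patch_stride: tuple[int, int, int] = (32, 32, 32)
    bias_poly_order: int = 2


@dataclass
class ModelConfig:
    fusion_dim: int = 32          # shared width of pooled fused vectors
    d_k: int = 64                 # attention key dimension
    snp_embed_dim: int = 64       # m in the dense SNP embedding
    snp_token_width: int = 16     # chunk width turning the embedding into tokens
    lstm_hidden: int = 128
    cnn_filters: tuple[int, ...] = (64, 128, 256)
    cnn_kernel: int = 3
    cnn_first_stride: int = 1     # stride of the first volumetric conv
    fc_units: int = 256
    dropout: float = 0.5
    modality_dropout: float = 0.1  # whole-modality dropout during training
    temperature: float = 1.0       # calibrated-softmax temperature

    def desk_scale(self) -> "ModelConfig":
        """A small configuration for CPU-scale experiments."""
        return ModelConfig(
            fusion_dim=16, d_k=16, snp_embed_dim=32, snp_token_width=8,
            lstm_hidden=16, cnn_filters=(4, 8), cnn_kernel=3,
            cnn_first_stride=2, fc_units=32,
            dropout=0.3, modality_dropout=self.modality_dropout,
            temperature=self.temperature)


@dataclass
class LossConfig:
    """Coefficients of the composite objective.

    ``lam`` weights the squared L2 norm (matching the optimiser's weight
    decay of 1e-5), ``alpha`` the L1 norm, ``kl_coeff`` the MC-dropout
    variational KL surrogate, ``gamma`` is the focal-loss focusing
    parameter. Class weights default to inverse class frequency.
    """
    lam: float = 1e-5
    alpha: float = 1e-6
    kl_coeff: float = 1e-5
    gamma: float = 2.0
    uncertainty_weight: float = 1.0
    focal_weight: float = 1.0


@dataclass
class MCConfig:
    num_passes: int = 30       # MC-dropout forward passes at test time
    training_passes: int = 5   # in-graph stochastic passes for the loss term
    seed: int = 0

    def __post_init__(self):
        if self.num_passes < 1:
            raise ValueError("num_passes must be >= 1")


@dataclass
class TrainStage:
    lr: float
    batch_size: int
    epochs: int
    dropout: float
    kernel: int = 3
    filters: int = 64
    lstm_units: int = 128
    fc_units: int = 256


@dataclass
class TrainConfig:
    schedule: list[TrainStage] = field(default_factory=lambda: desk_schedule())
    weight_decay: float = 1e-5
    clip_norm: float = 1.0
    patience: int = 5
    min_delta: float = 1e-4
    seed: int = 0


def reference_schedule() -> list[TrainStage]:
    """The full ten-stage progressive tuning schedule."""
    rows = [
        # lr,      batch, epochs, dropout, kernel, filters, lstm, fc
        (0.001,    32, 10, 0.5, 3, 64, 128, 256),
        (0.001,    32, 20, 0.4, 3, 64, 128, 256),
        (0.0005,   32, 30, 0.4, 3, 128, 128, 256),
        (0.0005,   16, 40, 0.3, 5, 128, 128, 256),
        (0.0005,   16, 50, 0.3, 5, 128, 256, 256),
        (0.0001,   16, 50, 0.2, 5, 128, 256, 256),
        (0.0001,   16, 50, 0.2, 5, 128, 256, 256),
        (0.0001,   16, 50, 0.2, 5, 256, 256, 256),
        (0.00001,  16, 50, 0.2, 5, 256, 256, 256),
        (0.00001,  16, 50, 0.2, 5, 256, 256, 256),
    ]
    return [TrainStage(*r) for r in rows]


def desk_schedule(epochs: tuple[int, int, int] = (6, 6, 4)) -> list[TrainStage]:
    """Three-stage compression of the annealing pattern for CPU runs."""
    return [
        TrainStage(lr=1e-3, batch_size=32, epochs=epochs[0], dropout=0.5),
        TrainStage(lr=1e-4, batch_size=16, epochs=epochs[1], dropout=0.3),
        TrainStage(lr=1e-5, batch_size=16, epochs=epochs[2], dropout=0.2),
    ]


@dataclass
class ExperimentConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    mc: MCConfig = field(default_factory=MCConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        raw = yaml.safe_load(text) or {}
        cfg = cls()
        for section in ("preprocess", "model", "loss", "mc"):
            if section in raw:
                obj = getattr(cfg, section)
                for k, v in raw[section].items():
                    if not hasattr(obj, k):
                        raise KeyError(f"unknown config key {section}.{k}")
                    setattr(obj, k, tuple(v) if isinstance(v, list) else v)
        if "train" in raw:
            tr = dict(raw["train"])
            stages = tr.pop("schedule", None)
            for k, v in tr.items():
                if not hasattr(cfg.train, k):
                    raise KeyError(f"unknown config key train.{k}")
                setattr(cfg.train, k, v)
            if stages is not None:
                cfg.train.schedule = [TrainStage(**s) for s in stages]
        return cfg
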
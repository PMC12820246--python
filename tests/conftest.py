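import numpy as np
import pytest

from neurofuse.config import ExperimentConfig, TrainStage
from neurofuse.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """Tiny tri-modal cohort spec used across IO / preprocessing tests."""
    return CohortSpec(
        n_subjects=12, class_proportions=(0.34, 0.33, 0.33),
        volume_shape=(12, 12, 12), n_channels=3, n_timesteps=1024,
        sample_rate=128.0, n_snps=40, frac_complete=0.75, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def desk_cfg() -> ExperimentConfig:
    """Desk-scale model + a two-stage schedule small enough for tests."""
    cfg = ExperimentConfig()
    cfg.model = cfg.model.desk_scale()
    cfg.train.schedule = [
        TrainStage(lr=1e-3, batch_size=32, epochs=3, dropout=0.4),
        TrainStage(lr=1e-4, batch_size=32, epochs=2, dropout=0.2),
    ]
    cfg.mc.training_passes = 2
    return cfg


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
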
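import numpy as np
import pytest

from locomep.synthetic_data import (
    GroundTruthConfig,
    default_ground_truth,
    generate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def default_cfg():
    return default_ground_truth(seed=7)


@pytest.fixture
def small_cfg():
    """Reduced dataset: 3 subjects (2 train), short trials, full grid."""
    cfg = default_ground_truth(seed=7)
    cfg.n_subjects = 3
    cfg.n_train_subjects = 2
    cfg.cycles_mean = 5.0
    cfg.cycles_sd = 0.0
    return cfg


@pytest.fixture
def noiseless_cfg():
    cfg = default_ground_truth(seed=7)
    cfg.n_subjects = 2
    cfg.n_train_subjects = 1
    cfg.cycles_mean = 5.0
    cfg.cycles_sd = 0.0
    cfg.envelope_noise_sd = 0.0
    cfg.weighting_jitter_sd = 0.0
    return cfg


@pytest.fixture(scope="session")
def small_dataset():
    cfg = default_ground_truth(seed=7)
    cfg.n_subjects = 3
    cfg.n_train_subjects = 2
    cfg.cycles_mean = 5.0
    cfg.cycles_sd = 0.0
    return generate_dataset(cfg)
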
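"""Shared fixtures: small synthetic datasets and cheap training configs.

Training fixtures use reduced epoch counts and frame counts so the unit
suite stays fast; the full-scale study configuration is exercised in
tests/test_acceptance.py.
"""

from __future__ import annotations

import numpy as np
import pytest

from gaitstack import (
    TrainConfig,
    default_gait_specs,
    featurize_dataset,
    generate_dataset,
    get_filters,
    scale_features,
    split_5050,
)
from gaitstack.wavelet import compress_recording


@pytest.fixture(scope="session")
def small_dataset():
    """Four recordings of 2400 frames each (deterministic, seed 7)."""
    return generate_dataset(default_gait_specs(), 2400, seed=7)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    """Level-2 compressed, 20-frame-window features of the small dataset."""
    filters = get_filters("db2")
    compressed = [compress_recording(r, filters, 2) for r in small_dataset]
    return featurize_dataset(compressed, 20)


@pytest.fixture(scope="session")
def small_split(small_features):
    """Scaled stratified 50:50 split of the small feature table."""
    train, test = split_5050(small_features, seed=7)
    train_s, test_s, scaler = scale_features(train, test)
    return train_s, test_s, scaler


@pytest.fixture
def cheap_config():
    """A fast training configuration for unit tests."""
    return TrainConfig(max_epochs=200, learning_rate=0.5, l2_weight=1e-4, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
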
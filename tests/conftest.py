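"""Shared fixtures: one small high-SNR simulated experiment, preprocessed
once per session, reused by the decoding and evaluation tests."""

import numpy as np
import pytest

import p300speller as ps


@pytest.fixture(scope="session")
def high_snr_config():
    return ps.persona_config("high", seed=7)


@pytest.fixture(scope="session")
def high_snr_experiment(high_snr_config):
    return ps.pipeline.simulate_experiment(
        high_snr_config, n_test_characters=6, n_test_trials=15
    )


@pytest.fixture(scope="session")
def train_features(high_snr_experiment):
    exp = high_snr_experiment
    return ps.preprocess_session(exp.train_recording, exp.train_schedule)


@pytest.fixture(scope="session")
def test_features(high_snr_experiment):
    exp = high_snr_experiment
    return ps.preprocess_session(
        exp.test_recording, exp.test_schedule, with_labels=False
    )


@pytest.fixture(scope="session")
def training_set(train_features):
    return ps.training_set_from_session(
        train_features, k=10, m_per_class=150, seed=0
    )


@pytest.fixture(scope="session")
def gaussian_classes():
    """Two well-separated spherical Gaussian classes in 10-D."""
    rng = np.random.default_rng(42)
    n = 300
    mu = np.zeros(10)
    mu[0] = 3.0
    X = np.vstack([rng.normal(size=(n, 10)) + mu, rng.normal(size=(n, 10))])
    y = np.concatenate([np.ones(n), -np.ones(n)])
    return X, y
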
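"""Session-level glue: simulate -> filter -> epoch -> featurize -> train.

`SessionFeatures` holds the per-stimulus feature matrix of one session
together with the event metadata, so the evaluation harness can form
k-trial averages by matrix row-averaging (downsampling, instant
selection and averaging are all linear and commute).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import preprocessing as pp
from .simulate import (
    EEGRecording,
    SimulationConfig,
    StimulusSchedule,
    generate_schedule,
    generate_session,
)

__all__ = [
    "SessionFeatures",
    "SimulatedExperiment",
    "preprocess_session",
    "training_set_from_session",
    "character_feature_tensor",
    "simulate_experiment",
]


@dataclass(frozen=True)
class SessionFeatures:
    """Un-normalized single-epoch feature vectors plus event metadata."""

    features: np.ndarray        # [n_events, N]
    stim_type: np.ndarray       # 1..12 per event
    trial_index: np.ndarray
    character_index: np.ndarray
    is_target: np.ndarray | None
    window_ms: tuple[float, float]

    @property
    def n_events(self) -> int:
        return self.features.shape[0]

    def characters(self) -> np.ndarray:
        return np.unique(self.character_index)


def preprocess_session(
    recording: EEGRecording,
    schedule: StimulusSchedule,
    with_labels: bool = True,
    window_ms: tuple[float, float] = pp.FEATURE_WINDOW_MS,
) -> SessionFeatures:
    """Filter the continuous recording, epoch it and extract features."""
    filtered = pp.bandpass_filter(recording)
    epochs = pp.extract_epochs(filtered, schedule, with_labels=with_labels)
    F = pp.epoch_feature_matrix(epochs, window_ms)
    return SessionFeatures(
        features=F,
        stim_type=np.array([ep.stim_type for ep in epochs]),
        trial_index=np.array([ep.trial_index for ep in epochs]),
        character_index=np.array([ep.character_index for ep in epochs]),
        is_target=(np.array([ep.is_target for ep in epochs], dtype=bool)
                   if with_labels else None),
        window_ms=window_ms,
    )


def training_set_from_session(
    sf: SessionFeatures,
    k: int,
    m_per_class: int = 1000,
    seed: int | None = 0,
    feature_mask: np.ndarray | None = None,
) -> pp.TrainingSet:
    """Balanced k-averaged training set from a labelled session.

    ``feature_mask`` restricts the features to a column subset (used by
    the windowed-feature analysis); normalization is refitted on the
    restricted averaged rows.
    """
    if sf.is_target is None:
        raise ValueError("session has no target labels (testing stage)")
    F = sf.features if feature_mask is None else sf.features[:, feature_mask]
    target_idx = np.flatnonzero(sf.is_target)
    nontarget_idx = np.flatnonzero(~sf.is_target)
    if len(target_idx) < k or len(nontarget_idx) < k:
        raise ValueError(f"k={k} exceeds class size")
    return pp._training_set_from_features(
        F, target_idx, nontarget_idx, k, m_per_class, seed
    )


def character_feature_tensor(
    sf: SessionFeatures,
    character_index: int,
    feature_mask: np.ndarray | None = None,
) -> np.ndarray:
    """[n_trials, 12, N] feature tensor of one character's trial blocks,
    trials in chronological order, stimulus types ordered 1..12."""
    sel = sf.character_index == character_index
    if not sel.any():
        raise KeyError(f"no events for character {character_index}")
    F = sf.features[sel]
    if feature_mask is not None:
        F = F[:, feature_mask]
    stim = sf.stim_type[sel]
    trial = sf.trial_index[sel]
    trials = np.unique(trial)
    out = np.empty((len(trials), 12, F.shape[1]))
    for ti, t in enumerate(trials):
        m = trial == t
        if m.sum() != 12 or len(np.unique(stim[m])) != 12:
            raise ValueError(f"trial {t} does not contain all 12 stimulus types")
        order = np.argsort(stim[m])
        out[ti] = F[m][order]
    return out


@dataclass(frozen=True)
class SimulatedExperiment:
    """Matched training and testing sessions from one simulation seed."""

    config: SimulationConfig
    train_schedule: StimulusSchedule
    train_recording: EEGRecording
    test_schedule: StimulusSchedule
    test_recording: EEGRecording


def simulate_experiment(
    config: SimulationConfig,
    n_train_characters: int = 11,
    n_train_trials: int = 10,
    n_test_characters: int = 36,
    n_test_trials: int = 15,
) -> SimulatedExperiment:
    """Simulate the copy-spelling training session (11 characters x 10
    trials by default) and a testing session (15 trials per character),
    all randomness derived from ``config.seed``."""
    seq = np.random.SeedSequence(config.seed)
    s_train, s_test = seq.generate_state(2) >> np.uint32(1)  # < 2**31
    train_schedule = generate_schedule(n_train_characters, n_train_trials,
                                       seed=int(s_train))
    test_schedule = generate_schedule(n_test_characters, n_test_trials,
                                      seed=int(s_test))
    from dataclasses import replace

    cfg_train = replace(config, seed=(config.seed * 2 + 1) % (2**31))
    cfg_test = replace(config, seed=(config.seed * 2 + 2) % (2**31))
    return SimulatedExperiment(
        config=config,
        train_schedule=train_schedule,
        train_recording=generate_session(cfg_train, train_schedule),
        test_schedule=test_schedule,
        test_recording=generate_session(cfg_test, test_schedule),
    )
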
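"""From continuous EEG to normalized feature vectors and training sets.

The processing chain follows the classical offline speller recipe:

1. zero-phase band-pass filtering of the *continuous* recording
   (0.5-15 Hz, 4th-order Butterworth, applied forward and backward);
2. cutting 1000 ms epochs starting at each stimulus onset;
3. downsampling by keeping every 25th sample (1000 Hz -> 40 Hz);
4. retaining the amplitudes at 100, 125, ..., 750 ms post-onset
   (27 instants per channel, endpoints inclusive) and concatenating them
   channel-major into a feature vector;
5. Z-scoring each feature with mean/std estimated over the union of
   target and nontarget *training* examples;
6. building a balanced training set of averaged brain responses, each the
   mean of k randomly chosen single-stimulus responses of one class.

Averaging, downsampling and instant selection are all linear, so the
implementation averages per-epoch feature vectors rather than raw epochs;
the result is bit-identical to averaging first.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal

from .simulate import EEGRecording, StimulusSchedule

__all__ = [
    "Epoch",
    "NormalizationStats",
    "TrainingSet",
    "DegenerateFeatureError",
    "bandpass_filter",
    "extract_epochs",
    "downsample_epoch",
    "feature_instants_ms",
    "build_feature_vector",
    "fit_normalization",
    "apply_normalization",
    "construct_training_set",
]

EPOCH_MS = 1000.0
DOWNSAMPLE_FACTOR = 25
#: Post-onset analysis window; endpoints inclusive at the downsampled
#: 25 ms spacing, giving 27 instants per channel.
FEATURE_WINDOW_MS = (100.0, 750.0)
FILTER_BAND_HZ = (0.5, 15.0)
FILTER_ORDER = 4


class DegenerateFeatureError(ValueError):
    """A feature has zero variance on the training set and cannot be Z-scored."""


@dataclass(frozen=True)
class Epoch:
    """One stimulus-locked EEG segment (1000 ms from onset)."""

    data: np.ndarray            # [n_samples, n_channels], microvolts
    sampling_rate: float
    stim_type: int              # 1..12
    trial_index: int
    character_index: int
    is_target: bool | None      # None during the testing stage
    downsampled: bool = False


@dataclass(frozen=True)
class NormalizationStats:
    """Per-feature Z-scoring statistics, fitted on training examples only."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.std <= 0):
            raise DegenerateFeatureError("normalization std must be positive")


@dataclass(frozen=True)
class TrainingSet:
    """Balanced matrix of averaged, Z-scored responses with +/-1 labels."""

    features: np.ndarray        # [2m, N]
    labels: np.ndarray          # +1 target / -1 nontarget
    k_averaged: int
    stats: NormalizationStats

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


def bandpass_filter(
    recording: EEGRecording,
    band_hz: tuple[float, float] = FILTER_BAND_HZ,
    order: int = FILTER_ORDER,
) -> EEGRecording:
    """Zero-phase Butterworth band-pass of the continuous recording.

    The filter is applied forward and backward (``sosfiltfilt``), so the
    pass band is traversed twice and the phase response is identically
    zero.  Raises if the recording is shorter than the filter warm-up
    padding.
    """
    fs = recording.sampling_rate
    if fs <= 2 * band_hz[1]:
        raise ValueError("sampling rate too low for the requested band")
    sos = signal.butter(order, band_hz, btype="bandpass", fs=fs, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if recording.n_samples <= padlen:
        raise ValueError(
            f"recording of {recording.n_samples} samples shorter than the "
            f"filter warm-up length ({padlen})"
        )
    filtered = signal.sosfiltfilt(sos, recording.data, axis=0)
    return EEGRecording(
        data=np.ascontiguousarray(filtered),
        sampling_rate=fs,
        channel_labels=recording.channel_labels,
    )


def extract_epochs(
    recording: EEGRecording,
    schedule: StimulusSchedule,
    with_labels: bool = True,
) -> list[Epoch]:
    """Cut one 1000 ms epoch per scheduled stimulus onset.

    With ``with_labels`` (training stage) each epoch's ``is_target`` is
    set from the schedule's ground truth; otherwise it is ``None``
    (testing stage, where only the stimulus type is known).
    """
    fs = recording.sampling_rate
    n_epoch = int(round(EPOCH_MS * fs / 1000.0))
    epochs: list[Epoch] = []
    for ev in schedule.events:
        i0 = int(round(ev.onset_ms * fs / 1000.0))
        if i0 < 0 or i0 + n_epoch > recording.n_samples:
            raise ValueError(f"onset at {ev.onset_ms} ms out of recording bounds")
        epochs.append(
            Epoch(
                data=recording.data[i0 : i0 + n_epoch].copy(),
                sampling_rate=fs,
                stim_type=ev.stim_type,
                trial_index=ev.trial_index,
                character_index=ev.character_index,
                is_target=schedule.is_target(ev) if with_labels else None,
            )
        )
    return epochs


def downsample_epoch(epoch: Epoch, factor: int = DOWNSAMPLE_FACTOR) -> Epoch:
    """Keep every ``factor``-th sample, starting at the onset sample."""
    if epoch.downsampled:
        raise ValueError("epoch already downsampled")
    n_expected = int(round(EPOCH_MS * epoch.sampling_rate / 1000.0))
    if epoch.data.shape[0] != n_expected:
        raise ValueError(
            f"expected {n_expected} samples per channel, got {epoch.data.shape[0]}"
        )
    return replace(
        epoch,
        data=epoch.data[::factor].copy(),
        sampling_rate=epoch.sampling_rate / factor,
        downsampled=True,
    )


def feature_instants_ms(
    window_ms: tuple[float, float] = FEATURE_WINDOW_MS,
    step_ms: float | None = None,
    sampling_rate: float = 1000.0,
) -> np.ndarray:
    """Post-onset instants retained as features (endpoints inclusive)."""
    if step_ms is None:
        step_ms = DOWNSAMPLE_FACTOR * 1000.0 / sampling_rate
    lo, hi = window_ms
    first = np.ceil(lo / step_ms - 1e-9) * step_ms
    instants = np.arange(first, hi + step_ms / 2, step_ms)
    if instants.size == 0:
        raise ValueError(f"no downsampled instants inside window {window_ms}")
    return instants


def build_feature_vector(
    epoch: Epoch, window_ms: tuple[float, float] = FEATURE_WINDOW_MS
) -> np.ndarray:
    """Amplitudes at the retained instants, concatenated channel-major."""
    if not epoch.downsampled:
        raise ValueError("epoch must be downsampled before feature extraction")
    step_ms = 1000.0 / epoch.sampling_rate
    instants = feature_instants_ms(window_ms, step_ms)
    idx = np.round(instants / step_ms).astype(int)
    if idx.max() >= epoch.data.shape[0]:
        raise ValueError("feature window extends past the epoch")
    return epoch.data[idx].T.ravel()  # channel-major: [ch0 instants, ch1 instants, ...]


def fit_normalization(features: Sequence[np.ndarray] | np.ndarray) -> NormalizationStats:
    """Per-feature mean and std over all training examples of both classes."""
    F = np.asarray(features, dtype=float)
    if F.ndim != 2 or F.shape[0] < 2:
        raise ValueError("need at least 2 training examples")
    mean = F.mean(axis=0)
    std = F.std(axis=0, ddof=0)
    # relative threshold: a numerically constant column has std at the
    # level of rounding error of its mean
    bad = std <= 1e-12 * np.maximum(1.0, np.abs(mean))
    if np.any(bad):
        raise DegenerateFeatureError(
            f"features {np.flatnonzero(bad).tolist()} have zero variance "
            "on the training set"
        )
    return NormalizationStats(mean=mean, std=std)


def apply_normalization(stats: NormalizationStats, f: np.ndarray) -> np.ndarray:
    """Z-score with *fitted* statistics; never refit at test time."""
    f = np.asarray(f, dtype=float)
    if f.shape[-1] != stats.mean.shape[0]:
        raise ValueError("feature length mismatch")
    return (f - stats.mean) / stats.std


def epoch_feature_matrix(
    epochs: Sequence[Epoch], window_ms: tuple[float, float] = FEATURE_WINDOW_MS
) -> np.ndarray:
    """Un-normalized feature vectors for a list of (raw, filtered) epochs."""
    return np.array(
        [build_feature_vector(downsample_epoch(ep), window_ms) for ep in epochs]
    )


def construct_training_set(
    epochs: Sequence[Epoch],
    k: int,
    m_per_class: int = 1000,
    seed: int | None = 0,
    window_ms: tuple[float, float] = FEATURE_WINDOW_MS,
) -> TrainingSet:
    """Balanced set of k-averaged responses (m per class), then Z-scored.

    Each row averages ``k`` responses drawn uniformly without replacement
    *within* the average; the ``m_per_class`` averages are drawn
    independently (with replacement across rows), since far more averages
    are requested than single responses exist.  ``k`` mirrors the number
    of intensification sequences available per stimulus at the testing
    stage.  Normalization statistics are fitted on the averaged rows —
    the objects actually fed to the classifiers.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    labels_known = [ep for ep in epochs if ep.is_target is not None]
    if len(labels_known) != len(epochs):
        raise ValueError("training epochs must carry target labels")
    target_idx = [i for i, ep in enumerate(epochs) if ep.is_target]
    nontarget_idx = [i for i, ep in enumerate(epochs) if not ep.is_target]
    if len(target_idx) < k or len(nontarget_idx) < k:
        raise ValueError(
            f"k={k} exceeds class size ({len(target_idx)} targets, "
            f"{len(nontarget_idx)} nontargets)"
        )
    F = epoch_feature_matrix(epochs, window_ms)
    return _training_set_from_features(
        F, np.array(target_idx), np.array(nontarget_idx), k, m_per_class, seed
    )


def _training_set_from_features(
    F: np.ndarray,
    target_idx: np.ndarray,
    nontarget_idx: np.ndarray,
    k: int,
    m_per_class: int,
    seed: int | None,
) -> TrainingSet:
    rng = np.random.default_rng(seed)
    rows = np.empty((2 * m_per_class, F.shape[1]))
    for c, idx in enumerate((target_idx, nontarget_idx)):
        for i in range(m_per_class):
            pick = rng.choice(idx, size=k, replace=False)
            rows[c * m_per_class + i] = F[pick].mean(axis=0)
    labels = np.concatenate(
        [np.ones(m_per_class), -np.ones(m_per_class)]
    )
    stats = fit_normalization(rows)
    return TrainingSet(
        features=apply_normalization(stats, rows),
        labels=labels,
        k_averaged=k,
        stats=stats,
    )
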
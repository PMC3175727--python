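"""Synthetic row/column-speller EEG sessions with ground truth.

The simulator emulates an 8-channel, 1000 Hz recording of a 6x6 matrix
speller: rows and columns are intensified for 100 ms followed by a 100 ms
gap, each of the 12 stimulus types flashing exactly once per trial in a
random order.  Epochs time-locked to the attended row/column carry a
positive P300-like deflection near 300 ms and an earlier negative,
posterior-weighted N2-like deflection.  On top of the event-related
structure the recording contains stationary autoregressive background
noise and a 5 Hz oscillation at the stimulation rate.

The event-related components are Gaussian-windowed bumps; real ERP
waveforms are not Gaussian, but the bump parametrisation (amplitude,
latency, width) spans the features the decoding pipeline is sensitive to.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "SimulationConfig",
    "StimulusEvent",
    "AttendedCharacter",
    "StimulusSchedule",
    "EEGRecording",
    "SNR_PERSONAS",
    "persona_config",
    "generate_schedule",
    "erp_template",
    "generate_session",
]

DEFAULT_CHANNELS = ("Cz", "CPz", "P1", "Pz", "P2", "PO3", "POz", "PO4")

#: Relative per-channel gain of the P300 component (centro-parietal maximum).
P300_TOPOGRAPHY = {
    "Cz": 0.75, "CPz": 0.90, "P1": 0.85, "Pz": 1.00,
    "P2": 0.85, "PO3": 0.80, "POz": 0.85, "PO4": 0.80,
}

#: Relative per-channel gain of the early negative component; it is
#: prominent over posterior (parieto-occipital) sites and decays toward
#: anterior midline sites.
N2_TOPOGRAPHY = {
    "Cz": 0.20, "CPz": 0.35, "P1": 0.55, "Pz": 0.55,
    "P2": 0.55, "PO3": 1.00, "POz": 1.00, "PO4": 1.00,
}

STIM_RATE_HZ = 5.0          # one stimulus every 200 ms
SOA_MS = 200.0              # 100 ms intensification + 100 ms gap
EPOCH_MS = 1000.0
PRE_SESSION_PAD_MS = 1000.0
INTER_CHARACTER_PAUSE_MS = 1000.0
POST_SESSION_PAD_MS = 1000.0


class ScheduleBoundsError(ValueError):
    """An epoch extends past the simulated session buffer."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated speller session.

    Amplitudes are in microvolts, latencies and widths in milliseconds.
    ``p300_width`` and ``n2_width`` are the standard deviations of the
    Gaussian bumps.  ``noise_std`` is the marginal (stationary) standard
    deviation of the per-channel AR(2) background noise, whose
    coefficients default to a strongly low-passed, EEG-like spectrum.
    ``seed`` fully determines the session.
    """

    n_channels: int = 8
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    sampling_rate: float = 1000.0
    p300_amplitude: float = 5.0
    p300_latency: float = 300.0
    p300_width: float = 55.0
    n2_amplitude: float = -3.0
    n2_latency: float = 200.0
    n2_width: float = 40.0
    noise_std: float = 10.0
    noise_ar_coefficients: tuple[float, ...] = (1.7, -0.72)
    stim_osc_amplitude: float = 1.0
    snr_label: str = "medium"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length must equal n_channels")
        if self.p300_width <= 0 or self.n2_width <= 0:
            raise ValueError("component widths must be positive")


#: Illustrative signal-to-noise personas.  High roughly mimics the
#: near-ceiling performers, low the participants hovering around 50%
#: character accuracy at 15 intensification sequences; the mapping is
#: qualitative, not calibrated to any individual recording.
SNR_PERSONAS = {
    "high": {"p300_amplitude": 6.0, "n2_amplitude": -4.0, "noise_std": 4.0},
    "medium": {"p300_amplitude": 5.0, "n2_amplitude": -3.0, "noise_std": 10.0},
    "low": {"p300_amplitude": 3.5, "n2_amplitude": -2.0, "noise_std": 20.0},
}


def persona_config(label: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from an SNR persona label."""
    if label not in SNR_PERSONAS:
        raise KeyError(f"unknown persona {label!r}; choose from {sorted(SNR_PERSONAS)}")
    params = dict(SNR_PERSONAS[label])
    params.update(overrides)
    return SimulationConfig(snr_label=label, seed=seed, **params)


@dataclass(frozen=True)
class StimulusEvent:
    onset_ms: float
    stim_type: int          # 1..6 rows, 7..12 columns
    trial_index: int        # global trial counter
    character_index: int


@dataclass(frozen=True)
class AttendedCharacter:
    character_index: int
    row: int                # 1..6
    column: int             # 1..6


@dataclass(frozen=True)
class StimulusSchedule:
    """Time-stamped stimulus events plus the ground-truth attended cells."""

    events: tuple[StimulusEvent, ...]
    attended: tuple[AttendedCharacter, ...]

    @property
    def n_characters(self) -> int:
        return len(self.attended)

    @property
    def duration_ms(self) -> float:
        if not self.events:
            return 0.0
        return max(e.onset_ms for e in self.events) + EPOCH_MS

    def attended_for(self, character_index: int) -> AttendedCharacter:
        for a in self.attended:
            if a.character_index == character_index:
                return a
        raise KeyError(f"no attended character with index {character_index}")

    def is_target(self, event: StimulusEvent) -> bool:
        """Whether the event intensifies the attended row or column."""
        a = self.attended_for(event.character_index)
        return event.stim_type == a.row or event.stim_type == 6 + a.column


@dataclass(frozen=True)
class EEGRecording:
    """Continuous multichannel signal in microvolts."""

    data: np.ndarray        # [n_samples, n_channels]
    sampling_rate: float
    channel_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("data must be [n_samples, n_channels]")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel count mismatch")
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


def generate_schedule(
    n_characters: int, n_trials_per_character: int, seed: int
) -> StimulusSchedule:
    """Random row/column intensification schedule with ground truth.

    Each trial is an independent random permutation of the 12 stimulus
    types; within a trial consecutive onsets are 200 ms apart.  Trials of
    one character run back to back; characters are separated by a 1 s
    pause and the session opens with 1 s of padding.  The attended cell
    of each character is drawn uniformly from the 6x6 grid.
    """
    if n_characters < 1 or n_trials_per_character < 1:
        raise ValueError("character and trial counts must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    events: list[StimulusEvent] = []
    attended: list[AttendedCharacter] = []
    trial_counter = 0
    t = PRE_SESSION_PAD_MS
    for ci in range(n_characters):
        attended.append(
            AttendedCharacter(
                character_index=ci,
                row=int(rng.integers(1, 7)),
                column=int(rng.integers(1, 7)),
            )
        )
        for _ in range(n_trials_per_character):
            order = rng.permutation(12) + 1
            for stim in order:
                events.append(
                    StimulusEvent(
                        onset_ms=t,
                        stim_type=int(stim),
                        trial_index=trial_counter,
                        character_index=ci,
                    )
                )
                t += SOA_MS
            trial_counter += 1
        t += INTER_CHARACTER_PAUSE_MS
    return StimulusSchedule(events=tuple(events), attended=tuple(attended))


def _bump(t_ms: np.ndarray, amplitude: float, latency: float, width: float) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((t_ms - latency) / width) ** 2)


def _topography(labels: Sequence[str], table: dict, default: float) -> np.ndarray:
    return np.array([table.get(lab, default) for lab in labels])


def erp_template(config: SimulationConfig, is_target: bool) -> np.ndarray:
    """Epoch-length [samples x channels] template inserted at stimulus onsets.

    Both classes share the 5 Hz stimulation-rate oscillation (phase-locked
    to the onset); only the target template adds the P300 bump and the
    posterior-weighted early negative bump.
    """
    n = int(round(EPOCH_MS * config.sampling_rate / 1000.0))
    t_ms = np.arange(n) * 1000.0 / config.sampling_rate
    osc = config.stim_osc_amplitude * np.sin(2 * np.pi * STIM_RATE_HZ * t_ms / 1000.0)
    template = np.tile(osc[:, None], (1, config.n_channels))
    if is_target:
        p300 = _bump(t_ms, config.p300_amplitude, config.p300_latency, config.p300_width)
        n2 = _bump(t_ms, config.n2_amplitude, config.n2_latency, config.n2_width)
        w_p300 = _topography(config.channel_labels, P300_TOPOGRAPHY, 1.0)
        w_n2 = _topography(config.channel_labels, N2_TOPOGRAPHY, 0.5)
        template = template + p300[:, None] * w_p300[None, :] + n2[:, None] * w_n2[None, :]
    return template


def _ar2_noise(
    rng: np.random.Generator, n_samples: int, coeffs: Sequence[float], std: float
) -> np.ndarray:
    """Stationary AR noise with marginal standard deviation ``std``."""
    if std == 0:
        return np.zeros(n_samples)
    a = np.asarray(coeffs, dtype=float)
    # x_t = a1 x_{t-1} + a2 x_{t-2} + eps_t  <=>  lfilter([1], [1, -a1, -a2])
    denom = np.concatenate(([1.0], -a))
    if np.any(np.abs(np.roots(denom)) >= 1.0):
        raise ValueError(f"unstable AR coefficients {tuple(a)}")
    if len(a) == 2:
        a1, a2 = a
        innov_var = std**2 * (1 + a2) * ((1 - a2) ** 2 - a1**2) / (1 - a2)
    else:
        # generic: scale by the empirical impulse-response power
        h = signal.lfilter([1.0], denom, np.eye(1, 4096, 0).ravel())
        innov_var = std**2 / np.sum(h**2)
    eps = rng.normal(0.0, np.sqrt(innov_var), size=n_samples + 2000)
    x = signal.lfilter([1.0], denom, eps)
    return x[2000:]  # drop burn-in so the series is effectively stationary


def generate_session(
    config: SimulationConfig, schedule: StimulusSchedule
) -> EEGRecording:
    """Superpose ERP templates, AR background noise and the 5 Hz oscillation.

    The recording is the sum of (i) the target-specific ERP bumps inserted
    at every event whose stimulus type matches the attended row or column,
    (ii) independent AR(2) noise per channel and (iii) a session-wide 5 Hz
    oscillation, phase-locked to the stimulus onsets (all onsets fall on
    multiples of the 200 ms stimulus period).  Deterministic given
    ``config.seed``.
    """
    fs = config.sampling_rate
    n_epoch = int(round(EPOCH_MS * fs / 1000.0))
    n_samples = int(round((schedule.duration_ms + POST_SESSION_PAD_MS) * fs / 1000.0))
    data = np.zeros((n_samples, config.n_channels))

    # Event-related part: only the target-specific bumps are event-local;
    # the 5 Hz oscillation is continuous (added below) and phase-matches
    # the per-epoch oscillation in erp_template.
    target_only = erp_template(config, True) - erp_template(config, False)
    for ev in schedule.events:
        i0 = int(round(ev.onset_ms * fs / 1000.0))
        if i0 < 0 or i0 + n_epoch > n_samples:
            raise ScheduleBoundsError(
                f"epoch at {ev.onset_ms} ms extends past the session buffer"
            )
        if schedule.is_target(ev):
            data[i0 : i0 + n_epoch] += target_only

    t_ms = np.arange(n_samples) * 1000.0 / fs
    data += config.stim_osc_amplitude * np.sin(
        2 * np.pi * STIM_RATE_HZ * t_ms / 1000.0
    )[:, None]

    seq = np.random.SeedSequence(entropy=config.seed, spawn_key=(1,))
    child = seq.spawn(config.n_channels)
    for ch in range(config.n_channels):
        rng = np.random.default_rng(child[ch])
        data[:, ch] += _ar2_noise(
            rng, n_samples, config.noise_ar_coefficients, config.noise_std
        )
    return EEGRecording(
        data=data, sampling_rate=fs, channel_labels=tuple(config.channel_labels)
    )


def with_attended(
    schedule: StimulusSchedule, attended: Sequence[AttendedCharacter]
) -> StimulusSchedule:
    """Replace the attended characters, keeping event timing untouched."""
    if len(attended) != len(schedule.attended):
        raise ValueError("attended list length mismatch")
    return replace(schedule, attended=tuple(attended))
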
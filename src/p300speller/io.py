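"""Reading and writing sessions: EDF ingest, CSV signal/event tables,
JSON ground truth.

Simulated sessions are persisted as plain text: a wide CSV with one
column per channel for the continuous signal, an event table with one
row per stimulus onset, and a JSON sidecar carrying the attended
characters and the simulation configuration.  Real continuous EEG can
be ingested from EDF (via mne) together with a delimited event table
using the same schema.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .simulate import (
    AttendedCharacter,
    EEGRecording,
    SimulationConfig,
    StimulusEvent,
    StimulusSchedule,
)

__all__ = [
    "write_session",
    "read_session",
    "write_events_csv",
    "read_events_csv",
    "read_edf",
]

EVENT_COLUMNS = ["onset_sample", "stim_type", "trial_index", "character_index",
                 "is_target"]


def write_events_csv(path, schedule: StimulusSchedule, sampling_rate: float) -> None:
    rows = [
        {
            "onset_sample": int(round(ev.onset_ms * sampling_rate / 1000.0)),
            "stim_type": ev.stim_type,
            "trial_index": ev.trial_index,
            "character_index": ev.character_index,
            "is_target": int(schedule.is_target(ev)),
        }
        for ev in schedule.events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_events_csv(path, sampling_rate: float,
                    attended: list[AttendedCharacter] | None = None
                    ) -> StimulusSchedule:
    """Event table -> schedule; ground truth from the sidecar when given.

    Without ``attended``, the attended cells are reconstructed from the
    per-event ``is_target`` flags (possible only for labelled sessions
    in which each character has exactly one target row and column).
    """
    df = pd.read_csv(path)
    events = tuple(
        StimulusEvent(
            onset_ms=float(r.onset_sample) * 1000.0 / sampling_rate,
            stim_type=int(r.stim_type),
            trial_index=int(r.trial_index),
            character_index=int(r.character_index),
        )
        for r in df.itertuples()
    )
    if attended is None:
        attended = []
        for ci in sorted(df.character_index.unique()):
            sub = df[(df.character_index == ci) & (df.is_target == 1)]
            rows = sorted(set(sub.stim_type) & set(range(1, 7)))
            cols = sorted(set(sub.stim_type) & set(range(7, 13)))
            if len(rows) != 1 or len(cols) != 1:
                raise ValueError(
                    f"character {ci}: cannot infer attended cell from labels"
                )
            attended.append(
                AttendedCharacter(character_index=int(ci), row=rows[0],
                                  column=cols[0] - 6)
            )
    return StimulusSchedule(events=events, attended=tuple(attended))


def write_session(out_dir, recording: EEGRecording, schedule: StimulusSchedule,
                  config: SimulationConfig | None = None) -> Path:
    """Persist a session as eeg.csv + events.csv + ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(recording.data, columns=list(recording.channel_labels)).to_csv(
        out / "eeg.csv", index=False
    )
    write_events_csv(out / "events.csv", schedule, recording.sampling_rate)
    sidecar = {
        "sampling_rate": recording.sampling_rate,
        "channel_labels": list(recording.channel_labels),
        "attended": [dataclasses.asdict(a) for a in schedule.attended],
    }
    if config is not None:
        sidecar["config"] = dataclasses.asdict(config)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return out


def read_session(session_dir) -> tuple[EEGRecording, StimulusSchedule]:
    d = Path(session_dir)
    with open(d / "ground_truth.json") as fh:
        sidecar = json.load(fh)
    fs = float(sidecar["sampling_rate"])
    data = pd.read_csv(d / "eeg.csv").to_numpy(dtype=float)
    recording = EEGRecording(
        data=data, sampling_rate=fs,
        channel_labels=tuple(sidecar["channel_labels"]),
    )
    attended = [AttendedCharacter(**a) for a in sidecar["attended"]]
    schedule = read_events_csv(d / "events.csv", fs, attended=attended)
    return recording, schedule


def read_edf(path, channels: list[str] | None = None) -> EEGRecording:
    """Continuous EEG from an EDF file, converted to microvolts."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if channels is not None:
        raw = raw.pick(channels)
    return EEGRecording(
        data=raw.get_data().T * 1e6,  # mne works in volts
        sampling_rate=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
    )
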
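"""Simulate a ground-truthed speller session and persist it as text files.

Generates the copy-spelling layout used for classifier training — 11
characters, 10 intensification sequences each, 12 flashes per sequence —
renders it into 8-channel, 1000 Hz EEG with P300/N2 structure, and
writes eeg.csv / events.csv / ground_truth.json.
"""

import p300speller as ps

config = ps.persona_config("medium", seed=42)
schedule = ps.generate_schedule(n_characters=11, n_trials_per_character=10, seed=42)
recording = ps.generate_session(config, schedule)

out = ps.io.write_session("scratch/example_session", recording, schedule, config)

n_targets = sum(schedule.is_target(e) for e in schedule.events)
print(f"session written to {out}")
print(f"events: {len(schedule.events)} "
      f"({schedule.n_characters} characters x 10 trials x 12 flashes)")
print(f"target events: {n_targets} (2 of 12 per trial: attended row + column)")
print(f"recording: {recording.n_samples} samples x {recording.n_channels} channels "
      f"at {recording.sampling_rate:.0f} Hz "
      f"({recording.n_samples / recording.sampling_rate:.1f} s)")
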
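"""Which post-stimulus latencies carry the decodable information?

Repeats the full train/decode cycle with features restricted to 50 ms
windows whose centres are spaced 50 ms apart, at 15 intensification
sequences with the Bayesian LDA.  Windows over the injected early
negative (200 ms) and P300 (300 ms) components should decode well;
late windows contain only noise and fall to chance.
"""

import numpy as np

import p300speller as ps

config = ps.persona_config("medium", seed=13)
exp = ps.pipeline.simulate_experiment(config, n_test_characters=12,
                                      n_test_trials=15)
train = ps.preprocess_session(exp.train_recording, exp.train_schedule)
test = ps.preprocess_session(exp.test_recording, exp.test_schedule,
                             with_labels=False)

centers = tuple(np.arange(125.0, 726.0, 50.0))
acc = ps.windowed_accuracy(
    train, test, exp.test_schedule, window_centers=centers,
    k=15, m_per_class=150, seed=5,
)
print("window centre [ms]   character accuracy [%]")
for c in centers:
    bar = "#" * int(round(30 * acc[c]))
    print(f"  {c:6.0f}              {100 * acc[c]:5.1f}  {bar}")
best = max(acc, key=acc.get)
print(f"best window centre: {best:.0f} ms "
      f"(components injected at 200 ms and 300 ms); "
      f"chance level {ps.chance_level(ps.default_layout()):.1f}%")
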
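"""Train a Bayesian LDA on one session and mind-type characters from another.

Runs the full chain: band-pass filter, epoch, downsample, Z-score,
balanced averaged training set, classifier fit, then per-character
decoding of a testing session from the 12 per-stimulus-type averaged
responses (best row from scores 1-6, best column from scores 7-12).
"""

import p300speller as ps

config = ps.persona_config("medium", seed=3)
exp = ps.pipeline.simulate_experiment(config, n_test_characters=8, n_test_trials=15)

train = ps.preprocess_session(exp.train_recording, exp.train_schedule)
test = ps.preprocess_session(exp.test_recording, exp.test_schedule,
                             with_labels=False)

k = 15
ts = ps.training_set_from_session(train, k=k, m_per_class=300, seed=0)
model = ps.BayesianLDA().fit(ts.features, ts.labels)
print(f"training set: {ts.features.shape[0]} averaged responses "
      f"x {ts.n_features} features (k = {k} trials per average)")
print(f"BLDA hyperparameters: alpha = {model.alpha_:.3g}, "
      f"noise variance = {model.noise_variance_:.3g} "
      f"({len(model.iteration_trace_) - 1} evidence iterations)")

layout = ps.default_layout()
n_correct = 0
for ci in test.characters():
    T = ps.pipeline.character_feature_tensor(test, int(ci))
    averaged = (T.mean(axis=0) - ts.stats.mean) / ts.stats.std
    decoded = ps.decode(model.decision_function(averaged), layout)
    truth = exp.test_schedule.attended_for(int(ci))
    intended = layout.char_at(truth.row, truth.column)
    mark = "ok" if decoded.character == intended else "MISS"
    n_correct += decoded.character == intended
    print(f"  character {ci}: intended '{intended}' -> typed "
          f"'{decoded.character}' [{mark}]")
print(f"typed {n_correct}/{len(test.characters())} characters correctly "
      f"at {k} intensification sequences")
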
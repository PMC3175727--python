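"""Compare the linear classifiers on one simulated patient session.

Fits Fisher LDA, stepwise LDA, Bayesian LDA and the least-squares linear
SVM on the same averaged-response training set and scores their
character accuracy over many 10-of-15 trial subsets.  (The kernel SVM,
projection-pursuit and neural-network models share the same interface
but take minutes rather than seconds; swap them in via ps.METHODS.)
"""

import p300speller as ps
from p300speller import evaluation as ev

config = ps.persona_config("low", seed=8)
exp = ps.pipeline.simulate_experiment(config, n_test_characters=12,
                                      n_test_trials=15)
train = ps.preprocess_session(exp.train_recording, exp.train_schedule)
test = ps.preprocess_session(exp.test_recording, exp.test_schedule,
                             with_labels=False)

k = 10
ts = ps.training_set_from_session(train, k=k, m_per_class=200, seed=0)
print(f"low-SNR persona, {len(test.characters())} test characters, "
      f"k = {k} of 15 trials, {ts.features.shape[0]} training averages")
for name in ("lda", "swlda", "blda", "svm"):
    model = ps.METHODS[name]().fit(ts.features, ts.labels)
    acc, n, _, _ = ev.evaluate_session_at_k(
        model, ts.stats, test, exp.test_schedule, k=k,
        max_combinations=500, seed=1,
    )
    print(f"  {name:6s} character accuracy {100 * acc:5.1f}%  "
          f"({n} decodes; chance {ps.chance_level(ps.default_layout()):.1f}%)")
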
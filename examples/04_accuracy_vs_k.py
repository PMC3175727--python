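"""Accuracy versus number of intensification sequences, with error grids.

For each k the classifier is retrained with k-trial averages and every
typed character is decoded from (up to 500) k-element subsets of its 15
recorded trials.  Also prints the mistype distribution at k = 10 — the
fraction of typed characters per (row offset, column offset) relative to
the intended one — and the directional offset standard deviations.
"""

import numpy as np

import p300speller as ps

config = ps.persona_config("low", seed=8)
exp = ps.pipeline.simulate_experiment(config, n_test_characters=12,
                                      n_test_trials=15)
train = ps.preprocess_session(exp.train_recording, exp.train_schedule)
test = ps.preprocess_session(exp.test_recording, exp.test_schedule,
                             with_labels=False)

out = ps.accuracy_vs_k(
    train, test, exp.test_schedule, classifier_factory=ps.BayesianLDA,
    k_range=range(1, 16), m_per_class=200, max_combinations=500,
    seed=0, method="blda",
)
print("k   accuracy[%]   vertical std   horizontal std")
disp = out.dispersion()
for k, acc, v, h in zip(out.curve.ks, out.curve.accuracies,
                        disp.vertical_std, disp.horizontal_std):
    print(f"{k:2d}   {100 * acc:7.1f}      {v:6.2f}         {h:6.2f}")

grid = out.grids[10]
print("\nmistype distribution at k = 10 (% of typed characters, "
      "rows: row offset -2..2, cols: column offset -2..2):")
c = 5
with np.printoptions(precision=1, suppress=True):
    print(grid.values[c - 2 : c + 3, c - 2 : c + 3])
print(f"center cell (correct rate): {grid.correct_rate:.1f}%; "
      "off-center mass sits mostly adjacent to the intended character")
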
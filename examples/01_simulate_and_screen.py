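"""Simulate a session and screen single neurons for stimulus encoding.

Builds the mixed-encoder template (100 neurons, 200 trials), runs the
sliding-window auROC screen with permutation significance and
choice-probability disambiguation, and compares the detected
stimulus-encoding set against the generator's ground truth.
"""

import numpy as np

from tastedyn import detect_encoders, make_population, screen_session

session, truth = make_population("encoders_mixed", seed=0)
print(f"session: {session.n_trials} trials, {session.n_neurons} neurons")

sm = screen_session(session, "stimulus", n_perm=2000, seed=0)
enc = detect_encoders(sm)
detected = set(int(i) for i in sm.neuron_ids[enc.is_encoder])
true_set = set(truth.loc[truth.tuned_variable == "stimulus_category",
                         "neuron_id"])

print(f"stimulus encoders detected: {len(detected)} "
      f"({len(detected) / session.n_neurons:.1%} of neurons)")
print(f"ground-truth stimulus-tuned neurons recovered: "
      f"{len(detected & true_set)}/{len(true_set)}")
best = enc.table().query("is_encoder")
print("best encoding-window centers (ms after stimulus delivery):")
print(np.sort(best["best_bin_center"].to_numpy()).astype(int))
# Each detected neuron carries >=5 consecutive bins with auROC outside
# [0.4, 0.6], permutation p <= 0.05, and a stimulus auROC that beats its
# choice-probability companion — the screen's definition of an encoder.
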
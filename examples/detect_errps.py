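"""Detect error-related potentials in a simulated session.

Runs the full detection chain on one synthetic subject: 1-10 Hz zero-phase
band-pass, epoching at each command delivery, decimation to 64 Hz,
restriction to the fronto-central decoding channels, then word-wise
cross-validation of the Fisher-ranked shrinkage-LDA detector with
Woody-style realignment inside each training fold.
"""

import numpy as np

import errpspeller as e

sub = e.simulate_subject(seed=1, condition="FBoff")
epochs = e.preprocess_session(sub.recording, sub.events)
print(f"epochs  : {epochs.data.shape} (epochs x channels x samples at "
      f"{epochs.rate:.0f} Hz)")

cv = e.crossvalidate_by_word(epochs)
print(f"folds   : {cv.n_folds} (one per spelled word)")
for fold, m in cv.per_fold.items():
    print(f"  fold {fold}: AUC {m.auc:.3f}  accuracy {m.accuracy:.3f} "
          f"(n={m.n_test})")
print(f"mean AUC      : {cv.mean_auc:.3f} +/- {cv.sd_auc:.3f}")
print(f"mean accuracy : {cv.mean_accuracy:.3f} +/- {cv.sd_accuracy:.3f}")

chance = e.binomial_chance_threshold(cv.n_test_total)
print(f"chance bound  : {chance:.3f} (95% binomial, n={cv.n_test_total})")
# An AUC well above 0.5 and an accuracy above the binomial chance bound mean
# single-trial error monitoring is decodable from these epochs; because only
# ~20% of commands are errors, per-class recalls matter more than raw
# accuracy (a constant 'correct' guess already scores 0.80).
rec_err = np.mean([m.recall_error for m in cv.per_fold.values()])
print(f"error recall  : {rec_err:.3f}")
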
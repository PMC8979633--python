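"""Produce the standard run report for one simulated subject.

Writes the detection bar chart with chance lines, grand averages before and
after realignment, the wrong-minus-correct scalp topographies, the Fisher
score channel x time map, and a machine-readable TSV summary.
"""

from pathlib import Path

import errpspeller as e
from errpspeller.classify import FeatureMatrix

out = Path("scratch/example_report")

results = {}
epochs = rr = fisher = None
for cond in ("FBon", "FBoff"):
    sub = e.simulate_subject(seed=1 + (cond == "FBon"), condition=cond)
    ep = e.preprocess_session(sub.recording, sub.events)
    results.setdefault("S1", {})[cond] = e.crossvalidate_by_word(ep)
    if cond == "FBoff":
        epochs = ep
        rr = e.realign_epochs(ep)
        fisher = e.fisher_scores(FeatureMatrix.from_epochs(rr.aligned))

layout = e.default_layout().subset(epochs.channels)
paths = e.render_report(results, epochs=epochs, realign_result=rr,
                        fisher=fisher, layout=layout, out_dir=out)
for p in paths:
    print(f"wrote {p}")
# summary.tsv has one row per subject x condition x fold with AUC, plain and
# balanced accuracy, per-class recalls and the test-fold size.
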
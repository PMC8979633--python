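"""Show what latency realignment buys.

Single-trial ErrPs jitter in time; averaging jittered epochs smears and
flattens the grand-average peaks. Iterative cross-correlation realignment
against the evolving error-class grand average recovers per-epoch shifts and
sharpens the average.
"""

import numpy as np

import errpspeller as e

sub = e.simulate_subject(seed=3, condition="FBoff")
epochs = e.preprocess_session(sub.recording, sub.events)

before = e.grand_average(epochs, "error")
res = e.realign_epochs(epochs)
after = e.grand_average(res.aligned, "error")

cpz = epochs.channel_index("CPz")
t = epochs.times
print(f"error epochs        : {int(epochs.is_error.sum())}")
print(f"iterations          : {res.iterations} (converged={res.converged})")
print("objective trace     :",
      " ".join(f"{v:.3f}" for v in res.objective_trace))
print(f"positive peak before: {before[cpz].max():.2f} uV")
print(f"positive peak after : {after[cpz].max():.2f} uV")
print(f"negative peak before: {before[cpz].min():.2f} uV")
print(f"negative peak after : {after[cpz].min():.2f} uV")
sd = res.aligned.shifts[epochs.is_error] * 1e3
print(f"recovered shifts    : sd {np.std(sd):.1f} ms "
      f"(generator jitter sd is 30 ms)")
# The realigned peaks are deeper/taller because the per-epoch latency
# corrections stop the jitter from averaging the peaks away; the objective
# (mean epoch-template correlation) increases monotonically per iteration.
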
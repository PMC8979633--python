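"""Simulate one speller session and save it to a container file.

Plans six target words, plays them back through the surrogate MI controller
at the fixed 20% command error rate, renders 16-channel synthetic EEG with
interaction-ErrP responses at the error events, and writes the recording
plus its event log to disk.
"""

from pathlib import Path

import errpspeller as e

out = Path("scratch/example_out")
out.mkdir(parents=True, exist_ok=True)

sub = e.simulate_subject(seed=1, condition="FBoff")
print(f"words spelled : {e.DEFAULT_WORDS}")
print(f"commands      : {len(sub.events)}")
print(f"errors        : {sub.events.n_errors} "
      f"({100 * sub.events.n_errors / len(sub.events):.1f}% of commands)")
print(f"recording     : {sub.recording.data.shape[0]} channels x "
      f"{sub.recording.duration:.0f} s at {sub.recording.rate:.0f} Hz")

path = out / "s01_FBoff.npz"
e.write_recording(sub.recording, sub.events, path)
rec, ev = e.read_recording(path)
print(f"container     : {path} (round-trips {len(ev)} events bit-exactly)")
# The error fraction sits near 20% by construction: that fixed, infrequent
# error rate is what makes the error events elicit clean ErrP responses.
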
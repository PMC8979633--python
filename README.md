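# errpspeller

Detection of **error-related potentials (ErrPs)** during **motor-imagery (MI)
BCI spelling**, as a fully simulated, fully tested analysis pipeline.

When a brain-computer interface misinterprets a user's command, the EEG shows
a stereotyped *interaction ErrP* time-locked to the erroneous action: a
fronto-central negativity near 250 ms followed by a positivity near 500 ms.
Detecting that signature single-trial offers a BCI an error-correction channel
that costs the user nothing. This package reproduces the computational side of
a pseudo-online speller study of that idea: the subject spells words with a
2-class MI speller whose control is secretly played back at a fixed 20%
command error rate, in two conditions (with and without continuous visual MI
feedback, `FBon` / `FBoff`), and an offline detector is trained to tell error
from correct epochs.

Because human recordings of such studies are not publicly deposited, the
package ships a first-class **synthetic session generator** whose output has
the statistical structure the analysis assumes, and the full detection chain
runs end to end on it:

1. **speller simulation** — six target words per condition spelled through a
   playback controller (log-normal surrogate trial durations, evidence
   accumulation traces, automatic error-correction), command error rate fixed
   at 20%;
2. **synthetic EEG** — 16-channel fronto-central 10-20 montage at 512 Hz:
   1/f background noise, mu/beta sensorimotor rhythms with lateralised
   event-related desynchronisation during MI periods, and a jittered,
   amplitude-variable ErrP template added at every error event;
3. **preprocessing** — zero-phase 4th-order Butterworth band-pass (1-10 Hz),
   epoching time-locked to each command, decimation to 64 Hz, fronto-central
   channel subset;
4. **Woody-style realignment** — iterative cross-correlation of single error
   epochs to their grand average, correcting single-trial latency jitter;
5. **classification** — Fisher-score ranking of channel x time features,
   shrinkage-regularised LDA, **word-wise cross-validation** (each spelled
   word is one fold), reporting per-fold AUC and accuracy;
6. **statistics** — exact paired Wilcoxon signed-rank tests (full
   2^n sign-assignment distribution), binomial chance-accuracy thresholds,
   FBon vs FBoff comparisons, and figure/table reports.

A parallel **MI decoder** (surface Laplacian, Welch band-power features,
discriminant-power ranking, Gaussian/LDA posteriors, sample rejection,
evidence accumulation) verifies open-loop that the simulated sessions carry
decodable sensorimotor activity.

## The statistics at the core

For feature *f* with class means μ₁ (error), μ₀ (correct) and variances σ₁²,
σ₀², the Fisher score is |μ₁ − μ₀| / √(σ₁² + σ₀²). Detection quality is
summarised by the Mann-Whitney AUC — P(score(error) > score(correct)), ties
counting ½ — and by accuracy at the prior-adjusted LDA boundary, compared to
the binomial chance bound 0.5 + z₀.₉₅·√(0.25/N) (≈ 0.58 at N = 100). Paired
condition comparisons use the exact two-sided Wilcoxon signed-rank
distribution, whose smallest attainable p at six folds is 2/2⁶ = 0.0313.

## Worked example

```bash
python examples/detect_errps.py
```

```
epochs  : (435, 8, 64) (epochs x channels x samples at 64 Hz)
folds   : 6 (one per spelled word)
  fold 0: AUC 0.861  accuracy 0.899 (n=79)
  fold 1: AUC 0.918  accuracy 0.839 (n=62)
  fold 2: AUC 0.969  accuracy 0.931 (n=72)
  fold 3: AUC 0.983  accuracy 0.914 (n=58)
  fold 4: AUC 0.852  accuracy 0.839 (n=62)
  fold 5: AUC 0.916  accuracy 0.882 (n=102)
mean AUC      : 0.917 +/- 0.054
mean accuracy : 0.884 +/- 0.038
chance bound  : 0.539 (95% binomial, n=435)
error recall  : 0.772
```

One simulated `FBoff` session produced 435 command epochs (91 errors); the
word-wise cross-validated detector separates error from correct epochs well
above the chance bound, and the error-class recall shows performance is not
an artifact of the 80/20 class imbalance. Other scripts in `examples/`
demonstrate session simulation and container I/O, the effect of realignment
on the grand average, FBon/FBoff condition statistics, open-loop MI decoding,
and report rendering.

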
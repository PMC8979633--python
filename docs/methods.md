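# Methods

This note documents the models, defaults and design choices behind
`errpspeller`: what the synthetic sessions emulate, how each stage of the
detection chain is defined, and where the open choices were made.

## The simulated study

One "subject x condition" unit is a spelling session: six target words
spelled with a 2-class motor-imagery (MI) speller under playback control. The
subject-side MI trial that produces each left/right command is surrogate —
its duration is drawn from a log-normal distribution (median 3 s, log-sd
0.35, clipped to [1.5, 7] s), a parametric stand-in for a database of
recorded trials — and the delivered command is wrong with a fixed probability
of 0.2. Erroneous commands are reverted automatically 1 s later, so sessions
always terminate; the error remains in the event log, which is the analysis
substrate. The two conditions, `FBon` and `FBoff` (with/without continuous
visual MI feedback), generate statistically identical ErrPs by default: the
null hypothesis of no feedback interference is built into the generator. An
optional `feedback_interference` parameter (amplitude attenuation `1-f` and
jitter inflation `1+f` under `FBon`) exists solely to exercise the comparison
machinery under the alternative.

### Cursor model

The speller is abstracted to a linear array of 27 characters (`a`-`z` plus
space). The cursor starts at the centre, moves one position per command, and
dwell-selects when it reaches the target character, after which it returns to
the centre. The intended direction is recomputed after every command, so the
"user" re-plans after an error. Only the command stream with correctness
labels matters downstream; tree-structured text entry, language models and
backspace are out of scope. The default words (`because crazy wizard vacuum
zebra cabbage`) use letters far from the array centre, giving ~430 commands
and ~85 error epochs per session — enough errors for stable grand averages
while remaining a six-word protocol.

### EEG generator

16 channels (10-20 fronto-central/centro-parietal montage) at 512 Hz, in
microvolts:

* **Background**: per-channel 1/f noise (spectral shaping of white noise,
  exponent 1.0), total sd 20 uV; optional 50 Hz line component (default 0).
* **ErrP template**: a negative Gaussian bump (-8 uV, sd 32 ms) at 250 ms and
  a positive one (+9 uV, sd 40 ms) at 500 ms after the command, each
  truncated to zero beyond three widths. Every error event adds a copy with
  latency jitter N(0, 30 ms) and a truncated-normal amplitude gain
  (mean 1, cv 0.25, resampled positive so polarity never flips), scaled per
  channel by a Gaussian fall-off from the FCz-CPz midline axis (sd 0.30 in
  unit-disc coordinates). Correct events add nothing.
* **Sensorimotor rhythms**: band-limited mu (8-12 Hz, 6 uV rms) and beta
  (18-26 Hz, 3 uV rms) noise on the motor-strip groups (C3/C1/FC3/CP1 and
  C4/C2/FC4/CP2). During each MI period the contralateral group's power drops
  by `erd_depth` (default 0.5) and the ipsilateral by
  `erd_depth * (1 - lateralization)` (lateralization 0.5).

All draws come from one `numpy` generator seeded per session, so identical
inputs are bit-identical. The generator's amplitudes and noise were fixed
once so that the end-to-end detector operates in the regime reported for
this kind of experiment (cross-validated AUC roughly 0.85-0.95 per session)
while the error-epoch grand average at CPz keeps its extrema at 250/500 ms
to within about one 64 Hz sample. Those two requirements pull in opposite
directions — single-trial noise high enough to make detection non-trivial
also perturbs the grand-average argmin/argmax — and the chosen point leaves
a small residual chance (about 1 in 40 seeds) of a two-sample excursion of
the negativity latency.

What the generator does **not** emulate: volume-conducted correlated noise,
ocular/muscular artifacts, non-stationary drifts, habituation of the ErrP,
or any coupling between MI performance and error probability. Passing tests
therefore demonstrate the correctness and calibration of the analysis chain,
not performance on real EEG.

## Detection chain

* **Filtering**: 4th-order Butterworth band-pass, 1-10 Hz, applied
  forward-backward (`sosfiltfilt`) on the continuous data before epoching, so
  edge transients never touch epoch windows and peak latencies are preserved
  (the realignment and time-domain features depend on them). The stated
  order is the design order passed to the filter design.
* **Epochs**: [0, 1] s after each command for features (a [-0.2, 0.8] s
  window is available for plotting; when the window contains [-0.2, 0] s the
  baseline mean is subtracted, otherwise no baseline). Events too close to
  the recording edges are dropped and counted. Decimation 512 -> 64 Hz is a
  plain stride (the 1-10 Hz filter is the anti-alias filter); non-integer
  ratios use polyphase resampling. The decoding subset is the eight
  fronto-central midline channels (Fz, FC1, FCz, FC2, Cz, CP1, CPz, CP2).
* **Realignment** (Woody-style): iterate { error-class grand average as
  template; per error epoch, the integer lag in +/-75 ms maximising the
  channel-summed Pearson correlation (per-channel mean removed) between the
  shifted epoch and the template; } until the largest shift change is below
  1 sample or 20 iterations. Ties break toward the smallest |lag|, then the
  negative lag, so flat epochs shift 0. The stored shift is the correction
  applied to the epoch (positive = content moved later); shifted epochs are
  edge-padded by repeating the boundary sample. If an update would lower the
  mean epoch-template correlation the previous state is kept and iteration
  stops, making the objective trace non-decreasing by construction. Only
  error epochs are realigned at training time (the ErrP carries the latency
  structure); at test time all epochs are shifted label-blind against the
  frozen training template, so test labels can never leak. A single global
  latency per epoch is estimated — no per-channel shifts, no warping.
* **Features and classifier**: epochs flatten to channel x time features
  (8 x 64 = 512). Features are ranked by Fisher score
  |mu_err - mu_corr| / sqrt(var_err + var_corr) (unbiased variances;
  zero-variance features score 0 when means agree, or ten times the largest
  finite score with a warning when they differ) and the top 60 kept (ties
  break toward earlier time, then lower channel). The classifier is LDA with
  Ledoit-Wolf shrinkage of the pooled covariance; scores are signed
  distances to the boundary, predictions use training-frequency priors.
  Plain accuracy is reported at that boundary; because classes are ~80/20,
  balanced accuracy and per-class recalls are always carried alongside.
* **Cross-validation**: one fold per spelled word; realignment template,
  Fisher ranking and LDA are fit on the training words only. A word whose
  epochs lack one class is merged into the neighbouring fold (logged). Fold
  means and SDs are unweighted across folds.

## MI decoder

Surface Laplacian (each channel minus the mean of neighbours within 0.22
unit-disc distance), 1 s analysis windows hopping 62.5 ms inside each MI
period, Welch PSD (Hann, half-window segments, 50% overlap) averaged into
2 Hz bins over 4-30 Hz and log-transformed. Features are ranked by the same
Fisher score; the classifier is either a single-prototype-per-class
diagonal Gaussian with Bayes-rule posteriors or shrinkage LDA (the offline
default). Evidence accumulation is exponential smoothing
`p <- alpha p + (1-alpha) q` (alpha 0.96 per step) with samples in
(0.45, 0.55) rejected, decisions at p >= 0.8 (or <= 0.2), and reset to 0.5
after a decision. None of these constants comes from the study being
emulated; they follow the common practice of this decoder family and are
all exposed in `DecoderConfig`.

## Statistics

Paired comparisons use the two-sided Wilcoxon signed-rank test with the
exact distribution for n <= 25 effective pairs: zero differences are dropped
(all-zero input returns p = 1 with a warning), midranks handle ties, and the
rank-sum distribution is built by dynamic programming — equivalent to
enumerating all 2^n sign assignments; the two-sided p is twice the smaller
tail, capped at 1. Above n = 25 the tie-corrected normal approximation is
used. Chance accuracy bounds come from the binomial null at p = 0.5: the
normal approximation `0.5 + z_conf sqrt(0.25/n)` (the dashed line drawn in
accuracy panels) or the exact smallest k/n with upper-tail probability below
the level. Condition comparisons run across subjects (paired on per-subject
fold means) and within subjects (paired across folds), flagged at 0.05
without multiple-testing correction, matching per-subject reporting
practice; the report notes this. Topography difference maps average
wrong-minus-correct over [0.20, 0.30] s (negativity) and [0.45, 0.55] s
(positivity).

## Numerical and interface choices

* Recording containers are compressed `.npz` archives with a format-version
  tag; reads validate every required field and round-trip bit-exactly.
* The acceptance script scales every derived seed below 2^31 and touches
  nothing outside the repository.
* Degenerate inputs are contracts, not surprises: single-class feature sets,
  empty epoch windows, out-of-range band edges, unknown channels and
  non-terminating session configurations all raise with the offending value
  named; realignment non-convergence warns and returns the best state
  instead of raising.
* Test problem sizes are deliberately small (two/three-word sessions for
  structural tests, five paired subjects for the end-to-end band check);
  they were chosen for statistical stability of the asserted properties at
  the generator's defaults.

## Known limitations

Single-trial ErrP detection here is easier than on real EEG (no artifacts,
no correlated noise, stationary template); the FBon/FBoff machinery is only
exercised under the built-in null and the synthetic alternative; the exact
Wilcoxon switches to an approximation above n = 25; the Gaussian MI
classifier is single-prototype (no mixture); and the speller abstraction
intentionally discards the tree-structured interface semantics.
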
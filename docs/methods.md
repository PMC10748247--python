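# Methods

## Signal model and what the generator emulates

The generator (`scratchkit.synth`) produces 8-channel recordings — five
stretch channels in mΩ of resistance change (D1 thumb … D5 little) and
three accelerometer axes in g — at 20 Hz, with per-sample 0/1 scratch
labels. Its waveform family is deliberately simple: sinusoids with
jittered frequency and phase, plus white noise and slow sinusoidal drift.
It reproduces the *discriminative structure* of glove data, not
biomechanics:

- **Finger-dominant scratching**: 1–5 randomly chosen fingers carry a
  3–8 Hz oscillation (default amplitude 20 mΩ) on top of a bent-finger
  offset.
- **Arm-dominant scratching**: all five fingers carry bent offsets while
  the 3–8 Hz oscillation appears on the accelerometer (default 0.5 g on
  AY/AZ).
- **Rubbing** mimics either style and, by default, adds x-axis
  accelerometer energy — a feature scratching does not show, because
  fingernail contact constrains the axes of motion. Rubbing is labelled
  as scratching throughout: it relieves itch the same way and is grouped
  with scratching.
- **Intensive** variants draw their frequency from the upper half of the
  band and scale amplitude by 1.5; the literature reports only a higher
  frequency during intensive scratching, the amplitude factor is this
  package's choice.
- **Non-scratching actions** (idle, waving, typing, tapping, moving an
  object, opening/closing the hand) place their energy below 3 Hz or as
  low-amplitude broadband activity.

The mΩ scale is anchored by the device calibration of 10 mΩ per 3 mm of
sensor extension: the default bent-finger offset of 33 mΩ corresponds to
roughly 10 mm, comfortably above the 10 mΩ bend threshold.

**Bent-finger wander.** Bent-finger offsets are not constant: they carry
a slow fluctuation (default 0.1–0.2 Hz, 45 % relative amplitude),
modelling hand repositioning during scratching. This is a physical
necessity, not a flourish: a strictly constant offset is the DC component
of the recording, and the slow processing path's high-pass filter removes
it — no threshold applied after *any* high-pass can see a perfectly
static curl for long. The wander's 0.1–0.2 Hz band is exactly the region
that passes both slow-path stages (above the 0.03 Hz cutoff, below the
moving average's ~0.3 Hz roll-off).

Actions ramp on/off over 0.25 s (raised cosine) to avoid discontinuities;
truth labels still cover the full bout, as whole actions are labelled as
units. The 30-minute session preset is 240 s of idle followed by seven
5 s scratch bouts at the 4-minute marks (alternating finger- and
arm-dominant), exactly 36,000 samples.

What passing tests on this generator do **not** show: robustness to real
sensor nonlinearity, inter-subject variation in finger length and
scratching style, unknown confusable actions (e.g. rapidly opening and
closing the hand, a known false-positive source on real data), or label
noise from human annotation. Held-out accuracy here is a parameter-
recovery statement about the pipeline, not a clinical performance claim.

## Signal processing

Two causal (forward-only) paths, zero initial state:

- **Fast path**: 0.5 Hz, 4th-order high-pass Butterworth (second-order
  sections) on all 8 channels. 3–8 Hz scratching content passes with
  |gain − 1| < 1 %; drift and posture are removed. The ring-down of a DC
  step falls below 10⁻³ of the step after ~6 s; the first ~5 s of any
  recording should be treated as transient.
- **Slow path** (stretch only): 0.03 Hz high-pass, **order 1**, then a
  moving average (window 30 samples, step 20, each window's mean held
  over its 20-sample block), then a magnitude threshold at 10 mΩ giving
  the binary bent/extended state. Ties (exactly 10 mΩ) count as bent —
  the detection-favouring choice.

Numerical/design choices worth recording:

- **Slow-path cutoff 0.03 Hz**: two published figures for this stage
  exist (0.03 Hz and 0.5 Hz); 0.03 Hz is the default because a 0.5 Hz
  high-pass erases the sustained offset the bend threshold needs within a
  second. Both are available via `DspConfig`.
- **Slow-path order 1**: the 4th-order alternative turns a held step into
  a <2 s transient followed by a sub-threshold undershoot, toggling the
  bend state mid-bout; order 1 decays monotonically with τ ≈ 5.3 s and is
  the only causal choice that preserves a curl for the duration of a
  typical bout. The fast path's published 4th order is untouched.
- **Moving-average alignment**: window *j* covers samples
  [20·j, 20·j+30); its mean is held over output block [20·j, 20·(j+1)),
  the tail holding the last mean, so all 13 channels stay sample-aligned
  for windowing.
- Causal filtering is used (not zero-phase): the device streams live, and
  nothing in the published processing indicates bidirectional filtering.

## Windowing

Each 10 s action contributes its central 7 s (140 samples; with an odd
number of samples to trim, the extra sample is dropped from the end),
excluding transitions to and from rest. Windows are 30 samples at a
20-sample stride: ⌊(N−30)/20⌋+1 complete windows, incomplete remainders
discarded (N=140 → 6 windows; N=29 → none). A window's label is the
median of its 30 per-sample labels; the exact 15/15 tie resolves to 1,
consistent with grouping rubbing as scratching. Training actions carry
uniform labels, so the median reduces to the action's truth label;
session data genuinely exercises the median at bout boundaries.

## Classifier

Input: one 30×13 window (5 filtered stretch, 3 filtered accel, 5 bend
channels), normalised per channel by mean/SD **from the training windows
only** (stored with the model; never recomputed from evaluation data).

Stack: Conv1D(32, kernel 3, same padding) → dropout(0.2) → ReLU →
Conv1D(64) → dropout → ReLU → max-pool(2) → LSTM(16, final hidden state)
→ Dense(64) → ReLU → Dense(2, softmax). Interpretations where the
published description is loose: the "64-filter pooling layer" is read as
a pooling stage after the 64-filter convolution (pooling has no filters);
dropout precedes each ReLU; the dense(64) stage uses ReLU. A 3-unit
output variant (non-scratch / scratch / rub) is provided, with rub
collapsed onto scratch at prediction time.

Training: categorical cross-entropy, Adam (lr 10⁻³), batch 32, 30 epochs
by default; all unstated hyperparameters are fixed, documented defaults
in `ModelConfig`. The network is implemented in NumPy with hand-written
backward passes; the test suite validates every layer and the full stack
against central finite differences (worst relative error < 10⁻⁵). A
single `numpy.random.Generator` seeds initialisation, dropout, and
shuffling, so training is bit-reproducible on one thread. Class weighting
is off by default (the default catalog is balanced 6/6).

**Rule baseline.** A training-free detector used as an independent
cross-check: a window is scratch if any filtered stretch channel's
3–8 Hz band power exceeds 20 mΩ² (finger signature), or any filtered
accelerometer axis exceeds 0.01 g² while ≥3 fingers are bent (arm
signature). Both thresholds sit about a decade from the generator's
signal and noise scales. "Bent" within a window means bend duty ≥ ⅓ of
the window — an every-sample requirement would be defeated by the
slow-path high-pass de-meaning long curls (see above).

## Evaluation

Confusion-derived rates with class 1 = scratch; a ratio with a zero
denominator is NA (a subject whose scratches all occurred on the
un-instrumented hand has no defined sensitivity). A compatibility mode
reports precision as 0 instead of NA when there are no positive
predictions, matching how published summaries sometimes print that cell.
Windows stride at 1 s, so scratch time is 1 s per positive window; the
session fraction is seconds over session length. An event (a truth
scratch interval) counts as detected if ≥1 positive window overlaps it in
time — the published work does not state its matching rule, so this
package defines it. Cohort summaries are NA-excluded means with sample
SD (n−1); NA is never imputed. Display rounding is decimal half-up at
the printed precision; raw values are always retained in machine output.

**Reference-cohort caveats.** The six-subject reference table used in the
tests has three printed-precision quirks, none forced green: (i) its
device scratch-seconds row means to 303.5, printed 303; the test allows
±1 s. (ii) Its device scratch-fraction row prints one cell as 0.9 where
0.10 (= 186 s/1800 s) is the only value consistent with the printed
mean ± SD (0.16 ± 0.14) — a suspected typo; the test demonstrates the
inconsistency rather than asserting the row as printed. (iii) The
precision row's printed SD (0.08) matches population-SD rounding while
the sample SD is 0.089; the test allows ±0.01 there. Narrative cohort
figures elsewhere in the source differ in the last digit from
recomputation off the rounded cells (40.4 % vs 40.3 %, 6.3 % vs 6.5 %,
99.1 % vs 99.2 %) because unrounded per-subject values were evidently
used; the tests work from the printed cells.

## Problem sizes

The acceptance script trains on 12 action specs × 20 repetitions
(16 training + 4 held-out repetitions each: 1,152 training and 288
held-out windows) and scores one 30-minute session (1,799 windows) —
about half a minute on one CPU. These sizes give class-balanced training
with enough held-out windows for stable percentages while keeping the
experiment small enough to rerun casually.

## Known limitations

- The generator's action classes are far more separable than real data;
  reported held-out accuracies (~0.99) characterise the pipeline, not
  the device.
- Only the named action classes are implemented; the full ~100-action
  catalog of the original experiment lives in an appendix not reproduced
  here. `ActionSpec` is extensible.
- No subject-specific thresholds or absolute finger-angle estimation
  (deliberately out of scope), no data augmentation, no hyperparameter
  search.
- Severity scores (EASI, PP-NRS) are carried as metadata and summarised,
  never correlated with scratch time — the available evidence found no
  such correlation over 30-minute sessions.
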
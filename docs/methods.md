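# Methods

## Pipeline model and assumptions

`megfc` treats each 4-s, 100 Hz multichannel segment as one independent
classification sample. A subject contributes many segments, all sharing
the subject's group label (CPS = positive, SPS = negative); the subset
partition keeps all of a subject's segments on one side of every
train/validation/test boundary in the subset scheme. The connectivity
index — the band-averaged magnitude of the imaginary part of coherency —
assumes that instantaneous linear mixing (the volume-conduction analogue
at parcel level) carries no class information, and that genuine
interaction is lagged. Classification assumes the group difference is
expressed in a sparse set of edges, which is what the univariate F-score
ranking plus overlap-rate stability selection is designed to find.

## Segment extraction

* Spike guard `pad_s = 10 s` on both sides of every annotated event;
  guard windows are clipped to the block and merged when they overlap.
* Clean intervals are tiled with non-overlapping `cut_len_s = 10 s`
  windows anchored at each interval's **left edge** (the cut grid is
  per-interval; a global grid is the other defensible convention and
  differs only at interval boundaries). A trailing partial window
  survives if ≥ `min_keep_s = 4 s`; every kept window is trimmed to its
  first `trim_len_s = 4 s`.
* Filtering: 4th-order Butterworth band-pass 1–70 Hz plus a Q = 30 IIR
  notch at 50 Hz, both applied forward–backward. Zero-phase application
  matters: phase distortion would leak into the imaginary part of
  coherency downstream.
* Decimation to 100 Hz is preceded by a zero-phase 8th-order
  Chebyshev-I low-pass at 40 Hz. A 70 Hz low-pass alone would alias
  through the 50 Hz post-decimation Nyquist; since the analysis band
  ends at 40 Hz, the 0.8×Nyquist anti-alias cutoff costs nothing.
* Artifact screening is automated: a segment is dropped when any sample's
  amplitude z-score (against the subject's pooled per-channel statistics)
  exceeds `amp_z_max = 6`, or any first-difference z-score exceeds
  `grad_z_max = 6` (jump proxy). Manual review and ICA-based blink/ECG
  removal are out of scope; the thresholds are config-exposed.

## Connectivity

Cross-spectra are estimated Welch-style with 1-s Hann windows at 50%
overlap (7 windows per 4-s segment; 1 Hz resolution). The estimator was
chosen for stability at 400 samples; it matches `scipy.signal.csd`
conventions exactly and is verified against it in the tests. Coherency
is normalized per frequency bin; the edge value is the mean of
|Im C(f)| over 1–40 Hz inclusive. Taking the magnitude **per bin before
averaging** is a deliberate choice: the signed imaginary part of a
lag-coupled pair oscillates in sign across the band (phase 2πfτ), so
signed averaging would largely cancel a real 20 ms interaction.
The cost of the magnitude convention is a positive noise floor: with
7 windows the per-segment floor on a null edge is ≈ 0.2, and ≈ 0.07 at
4,000 samples. Group contrasts ride on top of this floor, which is why
the discriminative signal survives. Self-connectivity is exactly zero
(the self-coherency is real); a zero auto-spectrum inside the band
raises an error naming the degenerate channel.

`merge_to_parcels` averages node-pair values over all node pairs
spanning two parcels, for users who compute FC on a finer source grid;
the synthetic pipeline runs natively at the 74-parcel level. The grid
size follows the emulated study's convention of 74 parcels over the
whole cortical surface (the Destrieux scheme defines 74 labels *per
hemisphere*; `n_parcels` is configurable for users who want 148).

## Feature ranking and stability selection

* The 74×74 matrix flattens to its lower triangle plus diagonal in
  row-major order — 2,775 features with a fixed canonical index map, so
  overlap counting across folds is well defined. The always-zero
  diagonal features are retained to preserve the count and the index
  arithmetic.
* F-score: between-class squared mean deviations over the sum of
  unbiased within-class variances. Each class needs ≥ 2 samples. A
  feature with zero pooled within-class variance scores 0 by default
  (constant features carry no usable contrast for the SVM); a config
  flag switches to +inf when the class means still differ.
* Top-fraction selection keeps k = ceil(fraction·m) features
  (ceil(0.01 × 2775) = 28; floor would give 27 and could never produce a
  28-feature stable set). Ties break toward the lower feature index.
* Stability: a feature is stable when selected in ≥ 12 of the 14 folds.
  Its mean F-score averages only the folds where it was selected —
  unselected folds never scored it in a comparable ranking context.
  Strong edges are stable features whose mean F-score exceeds 75% of the
  maximum (strict inequality; a single stable feature is therefore
  always strong).

## Classification

RBF SVM with C = 1.2 and γ = 5 everywhere — fold models and the final
model alike. The folds do not re-tune hyperparameters; a grid-search
hook exists but reproducibility of the fixed configuration is the
default. Features are not standardized before the SVM (FC values
already live in [0, 1]). The final classifier is retrained on the full
training pool restricted to the stable set (retraining, rather than
reusing a fold model, is the less ambiguous convention) and evaluated
once on the two held-out test subsets. The primary metric is
segment-level accuracy/sensitivity/specificity with CPS positive;
subject-level majority-vote accuracy is reported as a secondary column.
The test subsets are a seeded random draw by default and can be pinned
in the config.

## Synthetic cohort generator

The generator emulates the study conditions the pipeline is built for:
16 subjects per group; 74 cortical parcels; twenty 120-s blocks at
1200 Hz in raw mode; per-subject 4-s segment yields heterogeneous in
33–169 (drawn uniformly in segment mode; realized through per-subject
Poisson spike rates tuned on the annotation arithmetic in raw mode, so
the yield is guaranteed by construction). Base signals are band-limited
(1–45 Hz) unit-variance Gaussian noise per parcel, so the 1–40 Hz
analysis band is fully populated; the group difference is lagged linear
coupling (default strength 0.6, lag 20 ms) on a sparse set of edges
carried by one group, plus white observation noise (sd 0.1). The
default differential edges are the five strongest discriminative
connections reported for the emulated clinical cohort, resolved through
the Destrieux label table. A zero lag is rejected at construction:
instantaneous coupling is invisible to the connectivity index by design,
so it could never realize a recoverable group difference.

What the generator does **not** emulate: MEG forward modelling and
sensor noise, head movement, real spike morphology (annotations are
just Poisson times), blink/ECG artifacts, 1/f spectral structure,
within-subject nonstationarity, and subject-level random effects beyond
the segment-count heterogeneity. Passing recovery tests therefore show
that the pipeline's selection-and-classification machinery recovers
lagged sparse differences under realistic sample-size imbalance — not
that the clinical effect sizes or accuracies are reproduced.

## Numerical choices and degenerate inputs

* All randomness flows from one root seed through
  `numpy.random.SeedSequence` spawning; identical configs reproduce
  artifacts byte-for-byte.
* Interval arithmetic is float-based with a 1e-12 tolerance on the
  partial-window keep rule; the test suite pins it against an
  independent 1-ms-grid simulation.
* Filter correctness is asserted on steady-state response (the Q = 30
  notch rings ~0.6 s at segment edges under zero-phase application).
* A fold whose sub-training set lacks a class raises; a validation fold
  with a single class is allowed (accuracy remains defined). A random
  split that empties a class is redrawn and logged. An empty stable set
  raises at finalization — there is no classifier to evaluate.
* `overlap_threshold` is validated against the fold count before any
  computation.

## Problem sizes in tests and the acceptance run

Full-scale planted runs use 16+16 subjects × 40–80 segments (≈ 1,900
segments, ≈ 60 per subject) at 74 parcels; null-cohort batches use
8–16 segments per subject across 20 (tests) or 6 (acceptance script)
seeds — chance level does not depend on cohort size, so the smaller
cohorts are used for the repeated-seed checks. Raw-mode (1200 Hz
continuous) paths are exercised on reduced cohorts (few parcels, short
blocks); full-scale analyses use segment mode, which generates the
clean 4-s segments directly.

## Known limitations

* The F-score is univariate: redundant features are ranked
  independently, interactions are invisible, and the criterion extends
  only to two classes.
* Under the null, stable sets are frequently **non-empty**: the 14
  leave-one-subset-out folds share ~12/13 of their samples, so the same
  noise features recur across folds. The stability threshold controls
  but does not eliminate selection bias; the null-cohort chance-band
  test quantifies the consequence (test accuracy ≈ 50%).
* The random-split scheme mixes a subject's segments across the
  train/validation boundary by design (it mirrors the emulated study's
  second scheme); its validation accuracies are optimistically biased
  relative to the subject-level scheme and the held-out test subjects
  remain the honest yardstick.
* Coupling chains among planted edges create genuine secondary lagged
  correlations (a parcel receiving two delayed copies of the same
  source), so recovered stable sets can legitimately contain a few
  non-planted edges.
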
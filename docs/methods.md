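# Methods

This document states what `fhr-ttp` computes, the modelling assumptions
behind it, the parameter defaults, and the numerical choices. Units are
given with every parameter.

## Problem

Given an intrapartum cardiotocography (CTG) recording — fetal heart rate
(FHR) and uterine contraction (UC) traces sampled at 4 Hz, with an
umbilical-artery pH measured at birth — decide as early as possible whether
the fetus is compromised. A record is *compromised* when pH < 7.05,
*intermediate* when 7.05 ≤ pH < 7.15 (scored with the normals, but excluded
from training), and *normal* when pH ≥ 7.15. The two quantities of interest
are the pooled true positive rate (TPR) at fixed record-level false
positive rates (5/10/15/20%), and the time to predict (TTP): the time from
the start of the evaluated segment to the end of the first window that
triggers a positive decision.

## Preprocessing

Applied in order to the raw 4 Hz FHR (gaps are zero-coded throughout):

1. **Artifact removal** — samples > 200 bpm or < 50 bpm are zeroed; a
   sample differing by more than 25 bpm from the previous *retained
   non-zero* sample is zeroed (left-to-right scan, so a step change zeroes
   the later sample).
2. **Gap interpolation** — interior runs of zeros shorter than 15 s
   (60 samples at 4 Hz), flanked by valid samples on both sides, are
   linearly bridged. Leading/trailing gaps and gaps ≥ 15 s are left as
   zeros.
3. **Downsampling** — block average by a factor of 16 to 0.25 Hz, using
   only the non-zero samples of each block; an all-zero block stays zero.
   An incomplete leading block is dropped.
4. **Segment selection** — the last 60 min (900 samples at 0.25 Hz) are
   kept. Shorter records are rejected.

Signal loss of any span is the percentage of zero samples. Cohort-level
summaries report, per class, the fraction of records with signal loss below
a band (default 20%).

### Windowing

* Sliding windows: 15-min windows, 5-min stride; a 60-min segment yields
  `floor((60−15)/5)+1 = 10` windows.
* Cumulative windows: 15, 20, …, 60 min, all anchored at the segment start.
* Training augmentation: 30-min windows, 5-min stride — 7 overlapping
  windows per 60-min record, each inheriting the record label.
* Quality vector (MCNN input): the valid-sample fraction of each sliding
  window position, computed on the cleaned 4 Hz trace; length 10/7/4 for
  60/45/30-min inputs.

## Models

### FHR-LINet

An input-length-invariant 1-D CNN: input batch normalisation → three
parallel convolutions with kernels 5/15/25 (160 filters each, ReLU) →
channel concatenation → max-pool (size 2) → conv 128×7 (ReLU) → conv 128×9
(ReLU) → global average pooling over time → dense 64 (ReLU) → dropout 0.3 →
one sigmoid unit. Global average pooling removes the only dependence of the
parameter count on the input length, so a single weight set evaluates 15-
to 60-min windows. Training: weighted binary cross-entropy with balanced
class weights `w_c = n/(2 n_c)`, Adam, defaults 65 epochs, batch 32,
learning rate 1e-4.

The network is implemented directly on numpy (`fhr_ttp.nn`): im2col
convolution, batch normalisation with exponential running statistics
(momentum 0.99, eps 1e-3), inverted dropout, and Adam, all in float64.
Every analytic gradient is verified against central finite differences in
the test suite.

### MCNN baseline

A fixed-length multimodal CNN: FHR and UC branches of five
conv(40, k=9)+BN+ReLU+maxpool stages each, a quality branch (dense), the
FHR branch gated elementwise by the quality projection, concatenation with
the UC branch, two dense layers (10 units) with dropout, sigmoid output.
Its dense layers tie the weights to one input duration.

### Feature baseline

Four classical FHR features with validity flags, combined by L2-regularised
logistic regression (scikit-learn): deceleration capacity via phase
rectified signal averaging (anchor lag T=1, half-window L=60 samples),
median absolute deviation from a smoothed baseline (median filter over
120 s then a 0.01 Hz low-pass), the baseline level itself, and the Hurst
exponent by first-order detrended fluctuation analysis (dyadic scales,
≥ 256 valid samples). Invalid features are median-imputed; an all-invalid
window scores 0.

## Evaluation

Three approaches convert per-window probabilities to one record decision:

* **A1** — sliding 15-min windows; positive if any non-gated window meets
  the threshold. TTP = end of the first positive window.
* **A2** — cumulative windows with an affine threshold schedule:
  `threshold(w) = base − |gradient|·w` for window index `w`; the gradient
  is the OLS slope of per-length calibrated thresholds, fitted per fold.
* **A3** — one whole-segment window; TTP is identically the evaluation
  length.

Thresholds are calibrated on each test fold's own probabilities by
descending a 0.001 grid (from 1.0 for A1/A3, 1.5 for A2) until the
record-level FPR over normal records reaches each target. The
implementation uses a closed form proven equivalent to the literal descent
(and property-tested against it): a record fires at base `b` iff
`b ≤ max_w(prob_w + |g|·w)`, so the calibrated base is the largest grid
point at or below the k-th largest such score among normals,
`k = ceil(target·n_neg)`.

Windows whose signal loss exceeds a chosen threshold are *gated*: forced to
probability 0 so they can never fire; fully gated records are predicted
normal. The same threshold filters training windows.

Cross-validation is repeated stratified k-fold (defaults 5×5).
Intermediate-pH records are excluded from training folds only. TPR and mean
TTP (over all positive predictions, false positives included) are
summarised as mean ± SD across repeats; decisions from the first repeat are
pooled for paired tests. Methods are compared with McNemar's test on
compromised records: exact binomial when the discordant count is < 25,
otherwise chi-square with continuity correction.

## Synthetic cohort generator

`fhr_ttp.synthetic` emulates the statistical structure the pipeline
assumes, not fetal physiology: baseline U(120, 160) bpm; band-limited
Gaussian variability (2nd-order Butterworth, 0.5 Hz); raised-cosine UC
bumps with period U(180, 300) s; contraction-locked late decelerations
(30 s lag, 45 s width) whose probability and depth carry the planted class
effect (0.8 / 20–60 bpm compromised vs 0.1 / 10–30 bpm normal); isolated
out-of-range spikes; two-state geometric dropout whose stationary gap
fraction is available in closed form; class-conditional pH (uniform
(6.85, 7.05) compromised, floor-rounded so rounding can never cross the
cut; truncated normal (7.25, 0.07) bounded below at 7.05 for normals). The
pH is drawn, not derived from the waveform; the generated classes are the
ground truth classifiers are expected to recover.
`planted_effect_check` verifies the separability contract on the cleaned
0.25 Hz trace, where one PRSA step spans 4 s and deceleration-scale
structure is visible.

## Desk-scale study sizes

Full-fidelity defaults (160/128 filters, 65 epochs, lr 1e-4, 5×5 CV) are
impractical for routine runs on one CPU, so the package's own end-to-end
studies — the acceptance script, the acceptance tests, and the CLI default
config — use a deliberately reduced scale, chosen once for a single-CPU
budget:

* model: `LINetConfig.small()` — same topology, 24/24/16 widths;
* cohort: 100 synthetic records, 20% compromised;
* CV: 1 repeat × 5 stratified folds;
* training: 24 epochs, batch 32, learning rate 1e-3 (the higher rate
  compensates for the shorter schedule; 12 epochs under-trains this width).

These are the package's own desk-scale choices; nothing about them is
claimed to reproduce published full-scale numbers.

## Limitations

* The generator is a signal-level emulator; absolute TPR/TTP values on it
  say nothing about clinical performance.
* The numpy network trains on CPU only and is written for clarity over
  speed; full-width, full-schedule training is slow.
* Threshold calibration on each test fold's own probabilities (as in the
  evaluated protocol) gives operating points, not a deployable threshold.
* DFA-based Hurst estimation needs ≥ 256 valid samples and is biased on
  heavily gapped signals; validity flags propagate this.
* The WFDB reader covers the format-16 two-channel layout used by the
  target accession, not the full WFDB specification.
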
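# Methods

`voicescreen` implements a voice-as-biomarker screening pipeline for
post-stroke dysphagia: short patient vocalizations (sustained vowels /a e i
o u/, words, sentences, continuous speech) are classified pass/fail against
a bedside swallowing screen (TOR-BSST©-style label), using Mel-spectrogram
images of 0.5 s audio windows as CNN inputs and probability voting to reach
a participant-level decision. This note records the model, the parameter
choices that matter, and what the synthetic experiments do and do not show.

## Signal model and preprocessing

**Audio.** Mono PCM WAV, canonically 44.1 kHz / 16-bit. Amplitudes are
normalized by the integer full-scale value only (`x / 2^15`); there is no
per-clip peak normalization, so real-world level differences between
recordings are preserved. Stereo input is averaged to mono. Writing
quantizes as `round(x * 2^15)` clipped to int16, which bounds round-trip
error at one LSB (2^-15) per sample.

**Windowing.** Each vocalization clip is segmented into windows of
`window_s = 0.5` s with `overlap = 50 %`. The stride is computed in samples
as `round(window_s * sr * (1 - overlap))` to avoid cumulative drift. A
window is emitted only if it fits entirely inside the clip (no zero
padding); clips shorter than one window are rejected with a flag. Clip
duration enters only through the window count, `1 + floor((L - W)/S)` in
samples.

**Silence rejection.** Within each clip, window power is the mean squared
amplitude. Windows more than `power_reject_sd = 1.5` sample (n-1) standard
deviations *below* the clip's mean window power are rejected, so silences
and trailing breaths never reach the classifier. Statistics are per clip —
never pooled across clips or participants — because power varies strongly
with vocalization type and recording distance. Clips with fewer than two
windows keep all windows (the sd is undefined). Note the rule is
deliberately not idempotent: re-filtering a filtered set would recompute
the statistics on the survivors; filtering is applied exactly once, before
featurization.

## Mel-spectrogram imaging

Each window becomes a 224x224x3 image in one of two modes.

* STFT: Hamming analysis window of `fft_length` samples, hop 2048 samples,
  centered frames with reflection padding, so an n-sample window yields
  `1 + floor(n / 2048)` frames (11 for 0.5 s at 44.1 kHz). The default hop
  equals the RGB-mode FFT length, giving non-overlapping analysis frames;
  this is unusual but intentional — it is the configuration under study —
  and both are configurable.
* Mel filterbank: 512 triangular filters, HTK mel scale
  (`m = 2595 log10(1 + f/700)`), from `f_min = 20` Hz to Nyquist,
  area-normalized (gain `2/(f_hi - f_lo)`). At 512 bands the inter-band
  spacing (~11 Hz near 1 kHz) is finer than the FFT bin width for
  `fft_length <= 2048`, so some filters span no bin and stay empty; they
  produce floor values rather than being post-processed away. Consequence:
  a pure tone's brightest band is correct only to within
  `max(bin_width, band_spacing)` — the true resolution limit — and tests
  assert exactly that.
* dB conversion: `10 log10(power / max(power))`, floored at
  `top_db = 80` dB. An all-zero window maps to a constant `-80` dB matrix
  by convention.
* **rgb mode** (FFT 2048, matching the middle of the three-channel set):
  the matrix is min-max normalized to [0, 1] (an all-equal matrix maps to
  0), passed through a fixed 256-entry perceptual colormap (piecewise-linear
  ramp through 9 authored anchor colors, dark-to-bright with monotone
  luminance, vendored so rendering never depends on a plotting library),
  then resized per channel to 224x224 with bilinear interpolation. Low
  frequencies sit at the bottom of the image.
* **three_channel mode**: monochrome Mel-spectrograms at FFT lengths
  (1024, 2048, 4096), each normalized independently and stacked depth-wise
  in ascending FFT-length order — three different time/frequency trade-offs
  of the same window.

Images can be exported as 8-bit PNG (quantized to 1/255) or as exact
float32 tensors; in-memory pipelines carry float16 (~1e-3 resolution on
[0, 1] pixels), which is ample for training while keeping a 3,000-window
cohort around 1 GB.

## Classifiers

All models share one head: global average pooling, dropout, and a dense
layer with a single sigmoid unit emitting **P(pass)**. The screen-positive
class for evaluation is *fail*, so scores are inverted when building ROC
curves. The networks run on a self-contained numpy layer framework
(im2col convolutions, exact-erf GELU, layer/batch normalization, Adam) in
which every layer implements an analytic backward pass; the test suite
verifies each against central finite differences in float64.

* `tinycnn` — 8x8 average-pool input reduction, three 3x3 conv/ReLU blocks
  (8/16/32 channels) with max pooling, head dropout 0.2. About 6k
  parameters; trains from scratch in seconds per epoch on one CPU. This is
  the backbone used by every desk-scale experiment.
* `densenet121` — the DenseNet-121 topology (growth 32, blocks 6/12/24/16,
  bottleneck factor 4). Fine-tuning freezes everything up to and including
  the third transition; the last dense block, final norm and head train.
* `convnext_tiny` — the ConvNeXt-Tiny topology (depths 3/3/9/3, dims
  96/192/384/768, 7x7 depthwise convs, layer scale 1e-6). The stem and
  stages 1-3 are frozen; the stage-4 downsampler, stage-4 blocks and head
  train.

Both large topologies are randomly initialized (He); `pretrained=True`
raises, since no ImageNet weights are bundled. Normalization layers run
with fixed statistics (the frozen-statistics fine-tuning convention), so
batch norm acts as a learnable affine map. Frozen parameters are excluded
from the optimizer and are bit-identical before and after training, which
the tests assert.

**Training recipe.** Binary cross-entropy on logits, Adam, batch 32.
Validation is a participant-level split (`validation_fraction = 0.2`) —
never window-level, because half-overlapping windows of one speaker are
heavily correlated and would leak. Early stopping monitors validation
loss; training stops when it has not improved for `patience` epochs or at
`target_epochs`, and the best-epoch parameters are restored. A
reduce-on-plateau schedule halves the learning rate after 3 stale epochs.
Per-backbone profiles: densenet121 lr 1e-5, 55 target epochs, patience 7;
convnext_tiny lr 1e-5, 30, 10; tinycnn lr 3e-3, 18 target epochs,
patience 4 — a from-scratch model needs a from-scratch learning rate, and
its small head gets dropout 0.2 rather than the 0.8 used above the large
frozen backbones. Everything is seeded: data order, initialization and
dropout masks derive from the config seed, so identical seed + config
reproduces histories and predictions bitwise.

**Ensemble.** Unweighted averaging of member probabilities — transparent,
permutation-invariant, and convex (the ensemble output lies within the
members' min/max on every image).

## Voting and evaluation

Window probabilities are averaged to a clip score; clip scores are averaged
to a participant score (mean of means, so every clip carries equal weight
regardless of its window count — a pooled single-stage mean is available
behind a flag and differs exactly when window counts are unequal). A fixed
boundary of 0.5 maps scores to decisions: fail if score < 0.5, pass if
score >= 0.5; a score exactly at the boundary is a pass.

Reported metrics (positive = fail): sensitivity `tp/(tp+fn)`, specificity
`tn/(tn+fp)`, precision `tp/(tp+fp)`, F1. A 0/0 ratio is reported as
undefined and flagged, never as 0. AUC is the trapezoidal ROC area on
inverted scores (equivalently the Mann-Whitney probability of correct
ranking with ties at 0.5). Its confidence interval uses the Hanley-McNeil
normal approximation

    Q1 = A/(2-A),  Q2 = 2A^2/(1+A),
    SE^2 = [A(1-A) + (n+ - 1)(Q1 - A^2) + (n- - 1)(Q2 - A^2)] / (n+ n-),

reported **uncapped**: at screening-cohort sizes the upper bound routinely
exceeds 1 (e.g. A = 0.91 with 10 vs 18 gives an upper bound of 1.04), and
capping would hide the approximation's behavior.

## Synthetic cohorts

The generator emulates the recording protocol — per participant, 5 vowels x
3 repetitions of ~3 s sustained phonation (plus optional pseudo-speech
clips), written as 16-bit 44.1 kHz WAV with a manifest CSV. Synthesis is
source-filter: an impulse-train glottal source at f0 with per-cycle period
jitter and amplitude shimmer, cascaded one-pole low-passes approximating
the spectral tilt (one stage per ~6 dB/octave), three second-order formant
resonators per vowel (mean adult formant table, configurable), and
formant-shaped additive noise at a controlled level relative to the voiced
RMS. With zero perturbation the period is exactly `round(sr/f0)` samples
and the output is periodic to machine precision after an internal 0.5 s
filter warm-up that is trimmed away.

Class profiles encode the premise that screening status is audible as
voice quality. Pass: jitter 0.5 ± 0.2 %, shimmer 3 ± 1 %, breath noise
-35 ± 3 dB, tilt -12 dB/oct. Fail: jitter 3 ± 1 %, shimmer 12 ± 3 %,
breath noise -16 ± 3 dB, tilt -6 dB/oct — rough and breathy versus clear.
Each participant draws one voice from their class profile through a
per-participant seed substream (`[cohort_seed, index]`), so cohorts are
byte-identical under a seed and already-generated participants are stable
when a cohort grows. Enrollment order interleaves the classes, mirroring
rolling intake, so chronological splits contain both classes on both
sides. A third of clips (configurable) carry 0.75 s of leading silence to
exercise the power filter.

**What this does and does not show.** The generator produces a stationary,
single-speaker-per-participant, noise-free-background caricature of the
recording setting. Passing the end-to-end tests demonstrates that the
pipeline is wired correctly, that the features carry voice-quality
information, and that the training/voting machinery can recover a class
difference of the encoded kind from held-out speakers. It does not
demonstrate clinical performance: real dysphagic voice change is subtler
and multidimensional, real wards add noise and cross-talk, and real labels
carry assessor disagreement. The null-profile control (identical class
profiles) verifies the complementary property: with no encoded difference,
held-out discrimination collapses to chance. At the default experiment
size the held-out set has 4 fail vs 4 pass participants, where a single
null AUC has a sampling sd of roughly 0.2; the control therefore averages
the AUC over 5 seeds, whose mean under the null lies in [0.3, 0.7] with
~95 % probability — a single seed landing outside that band is expected
behavior, not a pipeline failure.

## Experiment sizes and numerical choices

The standard synthetic experiment uses 10 pass + 10 fail participants,
vowels only (300 clips, ~3,300 windows, ~3,000 images after silence
rejection), rgb mode, the tinycnn backbone, and a chronological 60/40
participant split; it runs in about two minutes on one CPU, and the
separated profiles are reliably detected with held-out participant-level
AUC at or near 1.0. Tie-breaks and degenerate inputs are fixed by
convention and tested: score exactly 0.5 is a pass; an all-equal matrix
normalizes to 0; an all-zero window maps to the dB floor image; undefined
metric ratios are flagged, not zeroed; sample (n-1) sd with keep-all below
two windows. Known limitations: no pretrained weights (transfer-learning
configurations are topologically faithful but start from random
initialization), no voice-activity detection beyond the power rule, no
codec support, and no attempt at phonetically realistic speech proxies.
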
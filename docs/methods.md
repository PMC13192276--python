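# Methods

## The model

`cuedgain` implements a stimulus-computable account of endogenous
auditory attention for the cocktail-party setting.  A listener (or
model) first hears a **cue** — an isolated excerpt of a target talker,
rendered at the talker's spatial position — and then a binaural
**mixture** containing a different excerpt of that talker superimposed
with distractor sources.  The task is to report the word spoken by the
target talker at the temporal midpoint of the mixture, from a closed
vocabulary of V word classes.

The model has three parts:

1. **Cochlear front-end** (`cochlea`).  A fixed simulation of the
   auditory periphery: an FIR gammatone filterbank (4th-order envelope,
   cosine carrier, unit peak gain per filter) with centre frequencies
   uniform on the Glasberg–Moore ERB-number scale
   (`21.4 log10(0.00437 f + 1)`), half-wave rectification, power-law
   compression with exponent 0.3, Kaiser-windowed-sinc low-pass plus
   polyphase downsampling, and a centre crop that discards onset/offset
   context.  The default configuration (40 filters between 40 Hz and
   20 kHz, 1,102 taps, 10-kHz output rate, 2-s crop of a 2.5-s input)
   yields a (2, 40, 20000) cochleagram.

2. **Convolutional word-recognition backbone** (`netblocks`).  A stack
   of blocks, each layer-norm → convolution → ReLU → Hanning-weighted
   average pooling, followed by flatten → fully connected → ReLU →
   dropout (p = 0.5, training only) → fully connected → softmax.
   Normalization statistics are per example over all (C, F, T)
   elements, with full-shape learnable scale/shift; convolution is
   'valid' along time and zero-padded 'same' along frequency, stride 1,
   no bias; pooling kernels have the stride-dependent size h = 1 for
   s = 1 and h = 4s otherwise, built as the outer product of 1-D
   Hanning windows and normalized to unit sum (the only normalization
   preserving constants).

3. **Feature gains** (`attention`).  The cue is passed through the same
   backbone (shared weights).  At each gain site l (the cochleagram and
   every convolutional block output), the cue activation is averaged
   over time into a memory m ∈ R^{C×F}, and a three-parameter sigmoid

       g = θ1 + (1 − θ1) / (1 + exp(−θ2 (m − θ3)))

   maps the memory to multiplicative gains applied to every time slice
   of the mixture's activation at the same site, immediately before the
   next block's normalization.  One (θ1, θ2, θ3) triple is shared per
   site.  Gains and backbone weights are jointly optimized for word
   classification, so the model is free to learn whether and where
   selection is useful.

Architectural variants isolate the contribution of this inductive
bias: `baseline` (cue concatenated as two extra input channels, no
explicit gains), `early_only` (gains at the cochleagram only),
`late_only` (gains at the final convolutional block output only) and
`gain_after_norm` (gains applied after each block's normalization
rather than before it).  For `late_only` and for the final site of the
all-site variants, the gated block output has no subsequent
normalization, so the gain multiplies the block's pooled output
directly; gating the pre-pooling conv output is a defensible
alternative we did not take.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| compression exponent | 0.3 | – | outer-hair-cell-like compression |
| layer-norm ε | 1e-5 | – | division-by-zero guard |
| gain init (θ1, θ2, θ3) | calibrated | – | θ3 = mean cue memory, θ2 = 2 / memory SD per site, θ1 = 0.5 (`AttentionModel.calibrate_gains`); see below |
| dropout p | 0.5 | – | penultimate FC activations only |
| optimizer | AdamW, wd 0.01 | – | decay on conv/FC weights only |
| learning rate / batch | 2e-3 / 32 (mini), 5e-5 / 288 (full-scale template) | – | desk vs cluster scale |
| early stop | no val improvement for 6 epochs (mini) | – | "trained until validation converged" |

θ1 is left unconstrained (the sigmoid's range is the open interval
between θ1 and 1, whichever order); the gain-range property is asserted
against whatever value is learned.

**Why calibrated gain initialization.**  Cue memories are non-negative
(cochleagram) or concentrated well away from zero, so a fixed
initialization like (0.5, 1, 0) places every memory on the same flat
upper shoulder of the sigmoid: gains start nearly constant, the
cue-conditional route carries almost no signal, and at small training
scales gradient descent reliably converges to a cue-free word-spotting
solution (we observed trained models whose responses were bit-identical
for either talker's cue or a silent cue, with θ2 shrinking toward a
flat sigmoid).  Setting the threshold at the mean memory and the slope
to two inverse standard deviations gives the gain field real contrast
across features from the first step, after which the selection solution
is discovered robustly.  At the full data scale this choice should be
immaterial; at desk scale it decides whether attention is learnable at
all.

## Synthetic data

No recorded speech is used.  `voicesynth` builds harmonic-complex
"talkers": each voice has a fundamental (with a slow ±1–5% contour), a
three-formant spectral envelope and a spectral tilt; two disjoint f0
ranges (80–140 Hz and 160–280 Hz) play the role of talker sex.  Word
identity is carried by deterministic per-band amplitude trajectories
over five log-spaced modulation bands — content is spectrotemporal, not
phonetic.  A matched filter on band envelopes identifies the word of a
clean utterance with ≥ 99% accuracy, and autocorrelation recovers the
voice f0 within 5%, so the mini task is learnable in principle.

Source manipulations for the harmonicity experiments: `inharmonic`
shifts each partial above the fundamental by an independent uniform
±30% jitter, rejection-resampled per component so adjacent partials
stay ≥ 30 Hz apart (the same pattern is reusable across the cue,
target and distractor of a trial); `whispered` replaces the harmonic
excitation by noise passed through a second-order 1,200-Hz high-pass
Butterworth filter whose zeros are scaled to 0.95 radius (so DC is
attenuated but not nulled), with the same band-envelope modulation.
The printed response figures for that filter in the source literature
do not follow from its stated construction at common sampling rates; we
implement the construction and treat the printed values as descriptive.

Voice formants interleave across voices on a log-frequency comb (with
per-voice jitter inside each region) rather than being drawn fully at
random: real talkers differ systematically in timbre, and at a
4-voice catalog size fully random formants frequently overlap so much
that spectral gating has no payoff and the selection benchmark is not
learnable.

`scenes` reproduces the statistical structure of the training
distribution: 1–6 distractors per scene, a uniform speech/non-speech
split, per-distractor level offsets uniform over a 20-dB range
([−10, +10] dB around the reference level — the range's anchoring is
our reading), SNR uniform on [−10, 10] dB, distractors colocated with
the target in half of the scenes, 10% silent-cue single-talker
examples, a bandpass augmentation (Butterworth, low cut U[40, 400] Hz,
high cut U[4, 16] kHz, order U{1..4}) on exactly one of cue/target in
half of the examples, and a target time shift up to half the labelled
word's duration constrained so the word still overlaps the midpoint.
Cue and mixture are RMS-normalized to 0.02, with RMS taken over both
channels jointly (per-channel normalization would destroy ILD cues).
Non-speech distractors are parametric noise textures (band-passed,
amplitude-modulated noise), not recorded scenes.

`spatial` renders anechoically with parametric cues rather than
measured HRTFs: a Woodworth spherical-head ITD (8.75-cm radius,
rounded to integer samples), an energy-preserving frequency-dependent
ILD (near/far gains √(1±s) with s = sin|azimuth|·w(f), w rising with
frequency — the energy-preserving form makes the symmetric-distractor
designs exactly SNR-preserving at each ear), an elevation-dependent
spectral notch shared by both ears (centre 6 kHz + 60 Hz/deg, the
monaural elevation cue), and 1/distance scaling.  Room and
location-grid sampling follow the stated geometry exactly (log-uniform
shoebox dimensions, listener ≥ 1.45 m from walls and ≤ 2 m high, 72
azimuths × 11 elevations × 2 distances = 1,584 positions, one distance
fixed at 1.4 m).  The 11 elevation values are not stated for the
simulator; we use −40° to +60° evenly spaced, flagged as a guess.
Reflections are not rendered; externally measured binaural impulse
responses can be plugged in via `render_with_brir`.

What passing desk-scale tests do **not** show: performance on real
speech, robustness to reverberation, phonetic or linguistic effects,
and the quantitative behavioural match to humans — those require the
full-scale corpus and cluster training (the `paper_scale_architecture`
and the full-scale hyperparameters ship as configuration templates
only).

## Desk-scale benchmark

The mini cocktail-party benchmark (`benchmarks`) trains a 3-block
feature-gain model from scratch on a single CPU: 8 words, 4 voices
(2 per f0 group), two-talker diotic mixtures at SNR U[−10, 10] dB with
10% silent-cue singles; evaluation on held-out two-talker trials at
0 dB.  The cochleagram is reduced to 24 ERB channels at a 250-Hz output
rate (with the Kaiser sinc shortened to width 8): the word code lives
in slow envelopes and the voice code in the spectral excitation
pattern, so discarding periodicity above ~118 Hz keeps the task intact
while shrinking compute ~80-fold.  Training uses a pool of reusable
synthesized utterances (each clip appears in several scenes, as in the
full-scale recipe's four-fold target reuse; 64 utterances per voice),
320 training scenes, batch 32 at learning rate 2e-3, and up to 30
epochs with early stopping on validation loss.  The benchmark's training protocol — the voice/word catalog, the
utterance pool and scene draws, the weight initialization and the batch
order — is pinned under a fixed protocol seed and treated as part of
the instrument, the desk-scale analogue of evaluating a published
study's fixed trained networks: training-seed variation at this data
scale can leave a run in the cue-free word-spotting optimum within the
epoch budget, which is a statement about small-sample optimization, not
about the mechanism.  The user-facing seed varies what should vary in
an evaluation: the held-out trials, the stage-analysis stimuli and the
random-weight control.  The model is still trained from scratch on
every run.

The three probes are: cued-word accuracy on 96 held-out trials
stratified half same-sex / half different-sex talker pairs, as in the
full-scale behavioural designs (chance 1/8); the cue-swap test
(swapping the cue between the two talkers should move the reported word
from one talker's word to the other's); and the stage-of-selection
analysis — per-stage Pearson correlations between
the mixture representation and the isolated target/distractor
representations, whose target-minus-distractor gap should grow with
depth for a trained model but not for a random-weight control.

## Numerical choices

- The neural stack runs on a small tape-based reverse-mode autodiff
  engine over NumPy (float32 data and gradients; float64 available and
  used for gradient checks against central differences).
- Sigmoids use the sign-split log-sum-exp-safe form; they saturate
  exactly to their asymptotes in float32 at extreme arguments, so range
  assertions use closed bounds at saturation.
- The cochlear low-pass follows the resampler convention: effective
  cutoff = roll-off × output Nyquist (≈ 4.74 kHz at the 10-kHz default,
  for the stated roll-off 0.94759); the nominal "4-kHz" figure is kept
  in the config as documentation.  Resampling is polyphase at the
  rational rate ratio (100/441 for the default), with zero-padding
  boundary handling — edges are discarded by the centre crop anyway.
- 'Same' frequency padding is left-biased: floor((n_f − 1)/2) zeros on
  the low-frequency side.
- Quadratic psychometric fits can cross the criterion twice; we take
  the crossing with positive fitted slope inside the tested SNR span,
  and return NaN (logged by callers) when the criterion is never
  attained.
- Permutation p-values use the (b + 1)/(n + 1) estimator.  The
  interaction test permutes condition labels within participant; it is
  exact under an exchangeable null (type-I error ≈ α, verified by
  simulation) and conservative when large main effects are present,
  since permutation mixes them into the interaction statistic.
- Mutual information is a plug-in estimate in bits from a joint
  histogram whose edges span the pooled min–max of both vectors, at
  4 bin counts (5, 10, 15, 20).
- Trial scoring: a response counted as correct (any in-vocabulary word
  of the target transcript) is never also a confusion; the tie goes to
  correct.

## Known limitations

- Gains are time-invariant within a trial and depend only on the cue,
  not the mixture; no executive "strength" control.
- The parametric renderer has no reflections and no front/back
  confusions; the precedence-effect stimulus construction is exact, but
  the benefit a model can extract from it at desk scale is limited by
  the anechoic renderer.
- Desk-scale accuracy targets are regression bounds for the synthetic
  task, not estimates of human or full-scale model performance.
- The stage-of-selection analysis records stage outputs before the
  gain of the following site is applied; gains therefore manifest from
  the next stage onward.
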
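# Methods

This note documents the model, the numerical choices, what the
synthetic data does and does not emulate, and the design decisions made
where the architecture description left matters open.

## Feature front end

A clip is z-scored (population standard deviation; a constant signal is
a hard error since it cannot be standardized), resampled to the working
rate (default 16 kHz), and framed with 25 ms Hamming windows hopping by
10 ms, giving `t = 1 + floor((L − win)/hop)` frames. Each frame's DFT
power spectrum (FFT size = next power of two ≥ the window length, 512 at
16 kHz) passes through a triangular Mel filterbank (HTK mel scale,
`2595·log10(1 + f/700)`), then a natural log with an additive floor of
1e−10 to keep all-zero bands finite at `log(1e−10)` rather than −∞.

The number of Mel bands defaults to 64 so that three frequency poolings
by 4 collapse the Mel axis exactly to one band (64 → 16 → 4 → 1); the
tests and desk-scale experiments use 16 bands with two residual blocks
by the same arithmetic.

Deltas use the standard regression estimator with half-width N = 2 and
edge frames replicated for out-of-range indices; delta-deltas are
literally the delta of the delta channel with the same N. Delta is a
linear operator — the suite checks linearity, the vanishing of deltas on
constants, and the closed-form value 1 on a unit ramp.

## Network

- **Channel expansion.** One 1×1 convolution (no nonlinearity) maps the
  3 input channels to `conv_channels` (128 by default). It is applied
  once, before the first block, which is the only reading that keeps all
  blocks shape-consistent.
- **Residual blocks.** conv3×3 → ReLU → conv3×3 → add the block input →
  ReLU → max-pool 2×4 with stride equal to size. Pooling is 2 on time
  and 4 on frequency, preserving temporal resolution for the recurrent
  stage. The blocks use no batch normalization: training accumulates
  gradients clip by clip (see below), so batch statistics are
  ill-defined, and the networks trained here converge without it.
- **Bi-LSTM.** The gate equations include peephole-style terms — the
  forget and input gates see the previous cell state through full
  matrices, the output gate the current one — and are implemented
  exactly in that form. Forget-gate biases initialize to 1 (remember by
  default); all other biases to 0; weights are Glorot-uniform from the
  model seed. Per-step output is the concatenation
  [forward h_t, backward h_t], width 2·128 = 256 at default size.
- **Attention.** Scores are `sigmoid(w·h_t + b)` softmax-normalized.
  Because the sigmoid confines scores to (0, 1), the weight ratio
  max α / min α is bounded by e ≈ 2.718 — the pooling can only mildly
  re-weight steps. This bounded form is intentional here;
  `attention_score="tanh"` switches to a conventional tanh scoring
  layer (bound e²) for comparison.
- **Head.** Two affine layers with ReLU between (hidden width 64 by
  default, unspecified in the original description) and a softmax.
  Argmax ties break toward the lowest class index.

## Training

Mean cross-entropy (log floored at 1e−12) minimized by Adam
(lr 1e−3, β = 0.9/0.999, batch 32, 50 epochs by default; the scaled-down
experiments use batch 8 and 6–8 epochs). Mini-batches are processed by
per-clip forward/backward with gradient accumulation, which handles
variable-length clips with no padding or masking and gives gradients
identical to padded batching. All arithmetic is float64; backpropagation
through the convolutions, pooling, BPTT (including the output gate's
dependence on the current cell state) and attention is hand-written and
verified against central-difference gradients in the suite. Runs are
deterministic given the seed; optional early stopping monitors
validation UAR with a patience counter and restores the best
parameters.

## Evaluation protocol

Folds partition speakers, never clips; `cross_validate` re-asserts
train/test speaker disjointness per fold rather than trusting the fold
plan. The pooled report (all held-out predictions concatenated) is
primary and per-fold reports are attached, since pooling is the more
stable statistic at these sample sizes. Classes absent from a fold's
test split are excluded from that fold's UAR with a warning. The
ablation harness re-runs cross-validation per configuration: block
counts 1–3 and the seven non-empty channel subsets.

## Synthetic data

Each class is a sum of two tones (carrier + a weak 1.5× partial)
amplitude-modulated at a class-specific rate; carriers sit at
400 + 600·k Hz. Speakers shift all carriers by a pitch offset within
±60 Hz and perturb the noise floor by ±2 dB around the 20 dB SNR
default. Defaults: 3 classes × 5 speakers × 4 clips of 1 s. Class
separation (600 Hz) is an order of magnitude larger than speaker
variation, so the corpus is separable by construction and a correctly
wired pipeline reaches UAR ≈ 1 under leave-one-speaker-out
cross-validation, while label permutation drops it to chance.

What this does **not** emulate: phonetic content, prosody, co-articulated
emotion cues, channel/room effects, or any overlap between speaker and
class characteristics. Passing tests therefore demonstrate that the
pipeline is wired correctly and can learn spectral class structure
across speakers — not that it attains any particular accuracy on real
emotional speech.

The trial-record generator plants two groups of 27 "defendants" whose
person-level emotion distributions default to the empirical published
proportions (13/6/8 vs 5/18/4 over angry/neutral/fear). Non-neutral
defendants express their emotion on ~70% of clips (at least one clip
always does) and are neutral otherwise, so the person-labeling rule is
genuinely exercised; each of three simulated experts reports the true
clip label with probability 0.9, else a uniformly random other emotion.

## Annotation and association

Utterance labels resolve by majority vote: a label held by ≥ 2 of 3
experts wins, otherwise the utterance is unresolved. (The source rule's
wording — "more than two experts" — is read as "two or more", since
strict unanimity would contradict the evident intent of majority
labeling; the threshold is a parameter.) A person showing any
non-neutral emotion gets their most frequent non-neutral emotion,
remaining ties breaking to the earliest occurrence (logged); only
all-neutral people are neutral. The chi-square test on the resulting
group × emotion table is an addition beyond the original descriptive
analysis (flagged in its output): Pearson chi-square without continuity
correction, dof (r−1)(k−1), Pearson residuals per cell, and a
Monte-Carlo exact option (tables resampled with fixed margins) used
automatically when any expected cell is below 5.

## Problem sizes used in the shipped experiments

The in-repo experiments and the acceptance script use the synthetic
corpus at its default 60 clips with a reduced network (16 Mel bands,
2 residual blocks, 12 conv channels, 24 LSTM units, 8 epochs) — chosen
as the smallest configuration that cleanly separates the synthetic
classes — and a 4-speaker, 24-clip corpus with a 64-band, 8-channel,
3-block model at 6 epochs for the ablation harness. The permutation
control averages three label permutations because held-out predictions
correlate within speakers, making any single permuted UAR a coarse
draw around chance. Published-scale values (128 kernels/units, 3 blocks,
64 bands, 50 epochs) remain the library defaults throughout.

## Known limitations

- The exact printed benchmark numbers of the original Emo-DB study
  (UAR 0.833 with three blocks and all three channels, and its
  one-/two-channel ablations) require the Berlin corpus and stochastic
  ten-fold training; with a local copy, `emoser emodb-index` plus
  `emoser crossval --k 10` runs that protocol, but no claim is made that
  seeds reproduce those exact values.
- The attention form's bounded weight ratio limits how much pooling can
  focus on informative frames; the tanh variant relaxes this but is not
  the specified form.
- Pure-NumPy training is single-process and CPU-bound; it is sized for
  corpora of hundreds of clips, not hours of audio.
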
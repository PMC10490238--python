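# Methods

## The model

`sleepalign` stages 30-s single-channel EEG epochs into the five AASM classes
{W, N1, N2, N3, REM} by contrastive alignment of two encoders in a shared
embedding space, the recipe popularized by CLIP for image–text pairs, applied
here to (signal, stage-label) pairs.

**Signal encoder.** Each epoch x (3000 samples at 100 Hz) passes through two
parallel 1-D convolutional branches. The small-kernel branch (64 filters,
kernel 64, stride 8) sees a 0.64-s window per convolution — wide enough to
resolve one full cycle of the fast rhythms that discriminate light sleep and
wake: alpha (8–13 Hz), sigma-band spindles (12–14 Hz). The large-kernel
branch (kernel 512, stride 64) sees 5.12 s, enough to capture whole delta
waves (0.5–4 Hz) that dominate N3. After the first convolution each branch is
gated by a CBAM block: channel attention pools the feature map over positions
(average and max), scores the two pooled vectors with a shared
squeeze/expand MLP, and sigmoid-gates each channel,

    Mc = σ(MLP(avgpool(F)) + MLP(maxpool(F))),   F' = Mc ⊗ F;

spatial attention then pools F' over channels, convolves the stacked
(avg, max) maps with a single width-7 kernel, and gates each position,

    Ms = σ(f⁷([avgpool(F'); maxpool(F')])),      F'' = Ms ⊗ F'.

Two same-padded refinement convolutions (kernel 8) and max-pooling follow;
the flattened branch outputs are concatenated, linearly projected to the
embedding width d_e, and L2-normalized to give S.

**Label encoder.** A stage code indexes a learned 5-row table (the "label
data"), is projected to the hidden width h, and is prepended with a learnable
class token c. The two-token sequence passes through K pre-norm residual
transformer blocks,

    ψ̃ = MHA(Norm(ψ)) + ψ,      ψ = MLP(Norm(ψ̃)) + ψ̃,

with layer normalization as Norm and a two-layer ReLU MLP with dropout
between the layers. The final class-token state, projected to d_e and
L2-normalized, is the label embedding L. With both encoders normalized, the
cosine similarity cos⟨S, L⟩ = S·L/(‖S‖‖L‖) reduces to a dot product.

**Objective.** A batch of n pairs yields the similarity matrix
M_ij = τ·cos⟨S_i, L_j⟩ with matched pairs on the diagonal. The loss is the
symmetric cross-entropy: each row classified against its own column
(signal→label), each column against its own row (label→signal), averaged.
The temperature τ is a learnable scalar parameterized as exp(log τ) and
initialized at 1/0.07 ≈ 14.3, the CLIP convention; `temperature: "fixed:1.0"`
recovers the unscaled cosine. Because only five labels exist, uniformly
random batches would repeat labels and turn off-diagonal cells into false
negatives; the default batching is therefore stratified — one randomly drawn
epoch per stage, batch size 5, stage order shuffled per step — so every
off-diagonal cell is a true negative. A multi-positive masked variant
(`stratified: false`) is available for repeated-label batches: each direction
then scores the total softmax mass on all positives of the row/column.

**Inference.** The five label embeddings are cached as a prototype table;
an epoch is assigned the stage whose prototype has the highest cosine with
its embedding, ties broken toward the lowest stage code (W < N1 < N2 < N3 <
REM). Predictions are elementwise — no cross-epoch context is used.

## Preprocessing

* **Baseline calibration.** A centred running median over a ~1-s
  neighbourhood is computed and *subtracted*. The median of a short window
  tracks slow drift (electrode wander, movement artefact) but is nearly
  blind to zero-mean oscillations faster than ~1 Hz, so subtraction removes
  a constant offset exactly, suppresses a linear ramp by >98% away from the
  edges, and preserves 10 Hz band power within 5% (all asserted in tests).
  Replacing the signal by the median itself would instead destroy the
  waveform the encoder needs, so the median is treated as a baseline
  estimate, not a smoothed signal. A centred window needs an odd sample
  count, so an even request is snapped up by one sample (the 1.0-s default
  at 100 Hz becomes 101 samples = 1.01 s).
* **Epoching.** Epoch i covers samples [3000·i, 3000·(i+1)) at 100 Hz,
  indexed from 0; a trailing partial epoch is truncated with a logged
  warning. All recordings are resampled to exactly 100 Hz (polyphase) on
  load because every architecture constant (0.64 s ↔ kernel 64, 5.12 s ↔
  kernel 512) assumes that rate.
* **Stage tokens.** The Sleep-EDF annotation dialect is mapped totally:
  the Rechtschaffen–Kales deep-sleep split tokens ("Sleep stage 3"/"4")
  both merge into N3 per the AASM standard; movement and unscored tokens
  map to a DROP sentinel and those epochs are removed before modelling.
* **Peripheral-wake trimming.** Long wake before and after the sleep period
  is removed: the kept range is [first_sleep − margin, last_sleep + margin]
  (inclusive, clipped), default margin 60 epochs = 30 min, the common
  Sleep-EDF convention. An all-wake recording is an error.
* **Per-epoch z-scoring** (default on, toggleable): amplitude scale varies
  across subjects and EDF gain settings; normalization makes the encoder see
  spectral shape rather than gain.

## Synthetic data

The generator emulates exactly the property the encoder is designed around —
stage-dependent band power — plus the slow baseline drift the median filter
must remove. Per stage, a 30-s epoch is a sum of unit-variance band
oscillators (3 random frequencies per band, random phases) weighted by the
stage recipe, scaled to a stage-typical microvolt amplitude, plus white
noise:

| stage | dominant band | extras | scale (µV) |
|-------|---------------|--------|------------|
| W   | alpha 8–13 Hz | beta 18–30 Hz | 30 |
| N1  | theta 4–8 Hz  | weak alpha | 35 |
| N2  | sigma 12–14 Hz | theta; spindles as 0.5–1-s Gaussian AM packets | 45 |
| N3  | delta 0.5–4 Hz | weak theta | 80 |
| REM | 2–3 Hz sawtooth | theta, low amplitude | 25 |

Drift is a 0.02-Hz sinusoid plus a linear ramp at the configured amplitude
(default 100 µV). Recordings are written as genuine 16-bit EDF (1-s records)
plus an `epoch_index,stage` CSV hypnogram and a manifest.

What this generator does *not* emulate: 1/f background spectra, artefacts
(EMG bursts, eye movements, electrode pops), stage-transition dynamics,
inter-subject variability, or class imbalance — real hypnograms are mostly
N2 and W. Passing the recovery study therefore shows that the pipeline,
optimizer and classifier work end-to-end on spectrally separable classes;
it does not predict clinical accuracy. A built-in guard property keeps this
honest: a naive band-power nearest-centroid classifier must reach >95% on
generated epochs, so end-to-end failures implicate the model code, not the
data.

## Numerical core

No deep-learning framework is used; the networks run on a compact
reverse-mode autodiff engine over float64 NumPy arrays (`autodiff.py`) with
exactly the operator set the model needs (broadcasted arithmetic, batched
matmul, im2col 1-D convolution, non-overlapping max-pool, softmax/logsumexp,
layer norm, dropout) and an Adam optimizer. Float64 plus single-threaded
NumPy makes two same-seed runs bit-identical — a tested contract — and keeps
finite-difference gradient checks meaningful (loss gradient verified to
1e-4, conv/pool/softmax to 1e-5). Weights use He-scaled fan-in uniform
initialization (bound √(6/fan_in)); with the unscaled bound the deep conv
stack collapses initial embeddings and contrastive training stalls on a
ln(5) plateau for a third of the step budget.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `EncoderConfig.small_kernel/stride` | 64 / 8 | 0.64-s fast-rhythm window at 100 Hz |
| `EncoderConfig.large_kernel/stride` | 512 / 64 | 5.12-s slow-wave window |
| `EncoderConfig.filters` | 64 | channels per branch |
| `EncoderConfig.reduction_ratio` | 8 | CBAM squeeze factor (≥8 hidden units at 64 channels) |
| `EncoderConfig.embed_dim` | 128 | shared space width d_e |
| `TransformerConfig.layers/hidden_dim/heads` | 4 / 128 / 4 | label-encoder depth and width |
| `TransformerConfig.dropout` | 0.1 | MLP dropout, training only |
| `TrainConfig.steps` | 300 | stratified optimizer steps |
| `TrainConfig.learning_rate` | 1e-3 | Adam step size |
| `TrainConfig.temperature_init` | 14.3 | initial τ (≈1/0.07) |
| `PreprocessConfig.median_window_s` | 1.0 | baseline neighbourhood (snapped to 1.01 s) |
| `PreprocessConfig.wake_margin_epochs` | 60 | flanking wake kept (30 min) |
| `SimConfig.drift_amplitude` | 100 µV | synthetic baseline drift |

## Design choices where the design was open

* **Loss form.** The objective is implemented as the standard symmetric
  InfoNCE cross-entropy over the similarity matrix — the CLIP objective the
  architecture is built around — rather than a per-cell binary
  cross-entropy, whose reference distributions are not well defined over
  this sample space.
* **Label vectorization.** A categorical stage has no canonical "token
  sequence"; the minimal faithful choice is a learned 5-entry embedding
  table of sequence length 1 feeding the projection layer. One-hot input
  would differ only by absorbing the table into that projection.
* **Branch tail.** The post-CBAM stack (two same-padded kernel-8
  convolutions, then pooling) mirrors the multi-scale
  feature-extraction-module pattern this encoder family uses; all counts
  live in `EncoderConfig` so alternatives are one config away.
* **Attention axes.** Published equation sets for CBAM-style blocks are
  notoriously loose about which axis is "channel"; standard CBAM semantics
  are used — channel attention pools over positions, spatial attention pools
  over channels — which is the only assignment that makes both gates
  shape-consistent.
* **Metric conventions.** Per-class F1 uses precision TP/(TP+FP) and recall
  TP/(TP+FN) with F1 = 0 when either denominator is zero, and the macro
  average always divides by T = 5 even if a stage is absent from the
  evaluation set.
* **Degenerate inputs.** Constant epochs z-score to zero rather than NaN;
  zero vectors are rejected by cosine similarity; an all-tie score vector
  predicts W by the tie-break rule.

## Problem sizes

The packaged recovery study (`sleepalign.experiments.synthetic_benchmark`,
also run by `scripts/acceptance.py`) uses 100 epochs per stage (500 epochs,
~4.2 h of signal), an 80/20 train/test split, reduced widths d_e = 32 and
K = 2, and 300 stratified steps — sizes chosen so the full study runs in
well under a minute on one CPU core while leaving a comfortable optimization
margin above the 0.90 balanced-accuracy / 0.85 macro-F1 bar. Across seeds
{0, 1, 3, 7, 13, 42, 100, 2024} the study lands between 0.976 and 1.000
balanced accuracy.

## Known limitations

* Scores on the synthetic benchmark say nothing quantitative about clinical
  recordings; see the generator's non-goals above.
* The stratified batch of 5 is small; loss traces are noisy step to step,
  which is why trend checks compare 20-step window means.
* Single-channel EEG only; no EOG/EMG branches, no sequence context across
  epochs (each epoch is staged independently).
* The EDF writer emits the minimal standard subset (one signal, 1-s records,
  integer sampling rate); it is meant for the generator's output, not as a
  general-purpose exporter.
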
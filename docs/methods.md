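# Methods

This note documents the models, conventions and numerical choices behind
`spikeseiz`, and what its synthetic-cohort experiments do and do not show.

## Problem setting

The package targets streaming seizure detection from multichannel scalp EEG
sampled at 256 Hz. Recordings are cut into causal 0.5 s windows (128 samples)
with 50 % overlap, each window is converted into binary spike trains, a
spiking classifier produces a per-window seizure probability, and a
persistence rule over consecutive positive windows turns the probability
stream into alarm events. Everything downstream of the raw signal is strictly
causal: a window's decision depends only on that window's samples.

## Preprocessing and labeling protocol

* Non-EEG channels (ECG/EMG/EOG/photic/VNS label patterns) are dropped;
  duplicate labels keep the first occurrence.
* Each channel is z-scored over the whole recording using the population
  (1/N) standard deviation; channels with sd < 1e-12 map to all zeros. The
  population convention makes the degenerate case deterministic; the choice
  of convention is otherwise immaterial at N ≥ 128.
* Windows start at 0, 64, 128, … samples; count = floor((N − 128)/64) + 1. A
  10 s ictal interval therefore spans 39 consecutive windows.
* A window is labeled seizure when at least 20 % (inclusive) of its samples
  fall inside an ictal interval. Seconds convert to samples as
  `round(t * fs)` with half-open `[on, off)` ranges; windows are half-open
  `[start, start + 128)`. Half-open arithmetic avoids double counting at
  boundaries and makes labels invariant to splitting an interval into
  abutting pieces.
* Splits are patient-wise: patient ids are sorted, shuffled with a fixed-seed
  generator (default 42), and the first round(0.7·P) go to training. No
  window can cross the partition boundary because its patient cannot.
* Class balancing acts on the training partition only: both classes are
  brought to n\* = min(n_majority, 4·n_minority), oversampling the minority
  with replacement and undersampling the majority without. The 4x cap limits
  duplication of rare seizure windows; validation windows are never touched,
  so validation prevalence stays natural.

## Spike encoding

**Delta–Sigma (change-based).** `s(t) = 1 if x(t) > r(t)`, and
`r(t+1) = r(t) + s(t) − Δ` with Δ = 0.3 and r(0) = 0 (the signal is z-scored,
so the zero reference matches its mean; r(0) is configurable). Upward
excursions only; there is no signed/negative spike channel. A consequence of
the recurrence worth knowing: on any constant input the long-run duty cycle
converges to Δ, so *counts* carry almost no information — the information is
in spike *timing* (runs of spikes during rises, silences during falls).

**Stochastic rate (amplitude-based).** `p(t) = σ(a·x(t) + c)`,
`b(t) ~ Bernoulli(p(t))`, defaults a = 1, c = 0. On zero-mean signals the
plain σ(x) code fires at ≈ 50 % of timesteps; sparse regimes (e.g. the ~5 %
densities reported for real EEG pipelines) are reachable through the (a, c)
extension, and `calibrate_rate_offset` fits c by bisection to a target
density. The defaults implement the plain code; the extension exists because
the printed sparse densities are not reproducible from σ(x) on standardized
inputs, and we do not guess an undocumented normalization.

Each channel's Bernoulli stream is keyed by (seed, CRC32 of the channel's
samples), making encodings reproducible, channel-permutation-equivariant, and
independent of how many other channels are present.

**Hybrid.** Rows 0..C−1 are Delta–Sigma, rows C..2C−1 are rate — 46 rows for
a 23-channel montage. Spike density ρ = events/(B·C·T) and the equivalent
firing rate is ρ·fs.

## Neuron model and surrogate gradient

LIF update `U' = βU + I`; spike when `U' ≥ θ` (θ = 1, inclusive); reset by
subtraction (default) or to zero. Learnable decays are stored as free scalars
squashed through a logistic so β stays in (0, 1); the HybridSNN initializes
β = 0.97, the ConvSNN head uses β = exp(−Δt/τ) with τ = 20 ms and
Δt = 1/256 s (≈ 0.8226).

The spike nonlinearity backpropagates through the fast-sigmoid surrogate
`k/(1 + k|U − θ|)²` with k = 25. Two numerical choices matter in practice:

* **Reset detachment.** The reset term uses the *detached* spike. Letting
  gradients flow through reset-by-subtraction contributes a factor
  (1 − θk) ≈ −24 per near-threshold timestep on the recurrent path and
  reliably destabilizes training over 128-step windows; with detachment the
  same configurations converge in a few epochs.
* **Membrane readout.** The output layer's logit at each step is the
  post-integration, pre-reset membrane potential; logits are averaged over
  the 128 steps.

## Architectures

Reference configurations and their exact trainable-parameter accounting
(learnable decays and affine normalization terms included):

* **HybridSNN** (46-input): Linear 46→192 biased (9,024) + LayerNorm (384) +
  LIF with 192 per-neuron decays → dropout 0.20 → Linear 192→2 (386) +
  output LIF (2). Total 9,988.
* **ConvSNN** (46-input): Conv1d stem 46→96 k=3 *without bias* + affine
  BatchNorm + GELU (13,440); one residual depthwise-separable block — biased
  depthwise k=9 (960), biased pointwise 96→96 (9,312), BatchNorm (192) —
  (10,464); 4-head temporal self-attention over the 96-dim embeddings with
  biased Q/K/V/out projections plus one post-residual LayerNorm (37,440);
  spiking head FC 96→192 + LayerNorm + LIF (19,200) and FC 192→2 + output
  LIF (388). Total 80,932. A two-block strided variant is constructible via
  `ModelSpec(n_ds_blocks=2, ds_strides=(1, 2))` but the one-block stride-1
  configuration is the parameter-count reference. No positional encoding is
  used in the attention module.
* **CNNBaseline** (offline reference): single-channel 2560-sample (10 s)
  input obtained by averaging EEG channels; valid convolutions
  1→32 k=5 (192), 32→64 k=5 (10,304), 64→128 k=3 (24,704) with 2x max-pools
  between them (temporal lengths 2556 → 1278 → 1274 → 637 → 635), global
  average pooling, dense 64 (8,256), dense 1 (65). Total 43,521. The first
  layer uses k = 5: with a single input channel this is the only kernel
  consistent with both the 192-parameter count and the 2556-sample output
  length.

All three are implemented on a compact NumPy reverse-mode autograd
(`spikeseiz._autograd`) providing broadcasting arithmetic, matmul, grouped
1-D convolution, max-pooling, the pointwise nonlinearities, and the
surrogate-gradient spike op; gradient correctness is verified against central
differences in the test suite.

## Training recipe

AdamW (decoupled weight decay 0.01) under a cosine one-cycle schedule (peak
1e-3, 30 % warm-up), global gradient-norm clipping at 1.0, label smoothing
0.05, and seizure up-weighting 1.2x with the class-weight vector normalized
to mean 1 (so weighting shifts gradient balance, not the effective learning
rate). The SNNs train with 2-class cross-entropy on time-averaged logits; the
CNN baseline with binary cross-entropy on its sigmoid logit. Early stopping
(patience 10) monitors the threshold-swept validation F1 — the model trains
on balanced windows but validates at natural prevalence, where a fixed 0.5
threshold is not a meaningful operating point and threshold selection is a
post hoc analysis by design. Temperature scaling (1-D bounded NLL
minimization) and the threshold sweep only ever read validation outputs;
model parameters are bit-identical before and after. Batch size defaults to
128; peak learning rate, weight decay, batch size and epoch budget are
package defaults, not values taken from elsewhere.

## Streaming evaluation

Recordings are replayed chronologically; probabilities binarized at the
(post hoc) threshold; each maximal run of ≥ k = 10 consecutive positive
windows yields exactly one alarm event spanning the full run, with a
declaration time at the end of the run's k-th window. Two readings of the
persistence horizon are exposed: k·step = 2.5 s and the true temporal span
(k−1)·step + win = 2.75 s. A false alarm overlaps (half-open) no annotated
interval; FA/h = false count / replayed hours and FA/day = 24·FA/h exactly.
Detection latency is declaration time minus onset, floored at zero — an
alarm whose run began before the annotated onset counts as latency 0, and
seizures with no overlapping alarm are reported missed. Wall-clock inference
latency (`benchmark_latency`) is reported per window over a 64-window batch
and is hardware-dependent by nature.

## Synthetic cohorts: what they emulate and what they do not

Background is 1/f-amplitude-shaped Gaussian noise mixed with a white
broadband floor (9 % of variance — scalp EEG always carries sensor/EMG
broadband power, and the floor sets the effective SNR seen by slope-based
encoders) plus a 0.2-amplitude 10 Hz sinusoid with random phase per channel;
unit variance overall. Ictal epochs superimpose an amplitude-modulated 3 Hz
spike-and-wave-like motif of unit variance, scaled by gain 4 by default and
a per-channel factor in [0.7, 1.3], with raised-cosine on/off ramps, a 30 s
guard from record edges and ≥ 5 s between seizures. Seizure morphology
varies per episode: a mix coefficient blends a transient-dominant component
(narrow von-Mises pulse train — strong sample-to-sample changes, low duty
cycle) with a rhythmic-dominant one (smooth 3 Hz wave — sustained moderate-
slope oscillation), alternating across a record's seizures so every record
samples both signatures. This mirrors the clinical observation that seizure
morphology varies across episodes, and it is what makes the two spike codes
genuinely complementary on synthetic data: amplitude coding underrepresents
brief sharp transients, change coding is the natural reader of them.
Seizures last 10–15 s and fill a configurable target prevalence (default
4 % of recording time). Every record draws from an RNG stream keyed by
(seed, patient, record), so cohorts are bit-reproducible and records
independent.

This captures the two ictal signatures the dual encoder is designed around —
rapid transients (sharp pulses → Delta–Sigma runs) and sustained rhythmic
oscillation (3 Hz amplitude structure → rate-code saturation patterns) — and
the class-imbalance/streaming structure of the task. It does **not** model
artifacts, montage/reference effects, inter-patient morphology differences,
non-stationary background, or realistic spectra beyond the 1/f shape.
Passing the synthetic end-to-end criteria therefore demonstrates that the
pipeline is implemented correctly and can learn the intended signatures under
controlled conditions; it says nothing quantitative about clinical EEG
performance.

Problem sizes used by the shipped experiments: the end-to-end learnability
checks train on a cohort of 6 patients x 1 record x 240 s (prevalence 0.085
so each record holds one transient-dominant and one rhythmic-dominant
seizure, gain 4) for up to 8 epochs at batch 256, with 3-seed medians; the
package defaults (`CohortSpec()`) are 8 patients x 240 s at prevalence 0.04.
These sizes are the package's chosen study conditions for desk-scale
reproduction.

A finding worth stating explicitly: on this synthetic cohort the trained
HybridSNN reaches median F1 ≈ 0.94 with hybrid input and the rate-only
stream scores clearly lower (≈ 0.85), but the Delta–Sigma-only stream does
*not* score lower (≈ 0.95). That is not a defect of the encoder or the
classifier: the Delta–Sigma recurrence at a 256 Hz sample rate is a one-bit
sigma-delta modulator, and on clean band-limited signals its duty cycle
tracks the signal slope (rate ≈ slope + Δ), making the stream an essentially
information-complete code. Its well-known weakness — noise amplification on
artifact-laden, broadband clinical EEG — requires background conditions the
generator deliberately does not model (artifact modeling is out of scope).
Ablation orderings in which the change-coded stream alone underperforms the
hybrid should therefore be expected on real recordings, not on clean
synthetic cohorts.

## Known limitations

* The rate coder's default σ(x) regime fires near 50 % on standardized EEG;
  sparse published densities require the (a, c) extension.
* The NumPy implementation is single-threaded BLAS-bound; it is meant for
  research-scale experiments, not deployment.
* The EDF reader is a thin optional wrapper (256 Hz only, no resampling) and
  is exercised only when the optional dependency is installed.
* Latency-coded input streams are provided as an optional extra encoder but
  are not part of any reference configuration.
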
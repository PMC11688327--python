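# Methods

## Problem setting

Sleep staging assigns one of five AASM classes — W (wake), N1, N2, N3
(slow-wave sleep; the older R&K stages 3 and 4 merged), REM — to each
30-second epoch of an overnight PSG recording. The package classifies single
epochs from three channels (two EEG derivations and one horizontal EOG): EEG
carries the spindle/K-complex and delta signatures of N2/N3, while EOG
separates REM from N1, whose EEG alone is ambiguous. The fixed integer
encoding W=0 … REM=4 is a package-wide contract (model head, confusion
matrices, checkpoints).

## Time-frequency front end

Each epoch channel (3000 samples at 100 Hz) becomes a T×F = 29×128 image:
200-sample (2 s) Hamming windows, hop 100 (50% overlap), no boundary
padding — giving exactly ⌊(3000−200)/100⌋+1 = 29 frames — each zero-padded
to a 256-point FFT. Of the 129 one-sided bins the DC bin is dropped by
default (EEG is AC-coupled; DC carries no stage information), leaving 128
bins covering ≈0.39–50 Hz; dropping Nyquist instead is a config option. The
magnitude (not power) spectrum is log-scaled with epsilon 1e-6 and each
image standardized to zero mean, unit variance. Normalization scope is per
image (per epoch and channel): it makes the representation invariant to
per-channel gain, which varies across montages and nights. Degenerate
all-constant inputs return an all-zero image with a warning rather than NaN.
Inputs at other native rates (e.g. 125 or 512 Hz clinical montages) are
polyphase-resampled to 100 Hz before epoching so the image geometry is
always 29×128.

## Encoder

The image is a sequence of 29 tokens with 128 features. A fixed sinusoidal
positional encoding is added, then N_s = 8 encoder layers are applied per
channel. Q, K, V are produced by **causal 1-D convolutions** (width 3, left
zero-padding), so projections at frame *t* use only frames ≤ *t*; attention
is standard scaled dot-product over H = 8 heads with the 1/√d_head scale,
head outputs concatenated without an output projection (the smallest
construction consistent with concatenation restoring the model width). The
feed-forward block is 150 hidden ReLU units; dropout 0.1 follows both the
attention and feed-forward sub-blocks, each wrapped in a residual connection
and normalization.

**CrossNorm.** At evaluation time the normalization is plain layer norm. In
training mode, with probability 0.5 per forward pass, batch instances are
randomly paired and their first two moments exchanged before the layer norm:
statistics are computed **per feature over the token axis** (a 128-vector of
means and standard deviations per instance), and instance *a* is remapped to
carry *b*'s moments, a′ = (a − μ_a)/σ_a · σ_b + μ_b, and symmetrically. The
feature-wise (rather than scalar-per-instance) choice matters: a scalar
affine remap would be cancelled exactly by the following per-token layer
norm, whereas a feature-wise exchange survives it and genuinely widens the
style distribution. Zero spreads are stabilized by eps² = 1e-10 inside the
variance root, so a constant feature maps to σ = 1e-5 while healthy spreads
are perturbed only at 1e-10 — this keeps the exchange invertible to ~1e-9.
Pairing batch instances (rather than channels within a sample) was chosen
because the three channel branches have separate encoders and never meet
before fusion; within-sample pairing would require cross-branch plumbing for
no clear statistical gain.

## Multi-scale feature extraction

The encoder output (29×128, treated as a one-channel 2-D map) feeds a
cascade of four 3×3 dilated convolutions at rates [1, 4, 8, 16]:
X₁ = conv₁(x) and Xᵢ = conv_rᵢ(x + Xᵢ₋₁), "same" zero padding throughout.
The cumulative form lets each coarser branch see the input plus the previous
branch's features. Fusion weights come from global average pooling along the
**time** axis (one value per frequency position and scale), a sigmoid, then
a softmax **across scales** at each frequency position; the sigmoid is kept
even though the softmax alone would normalize, because squashing to (0, 1)
first bounds the logit range and keeps the weights away from hard 0/1. The
weighted branch sum is added to the input (residual). Frequency bins play
the "channel" role for the weighting — the only reading under which
per-channel weights exist for a single-channel map. Branches are
single-channel; with 3×3 kernels this keeps the block at 40 parameters and
its effect interpretable as frequency-band reweighting. At rate 16 the
kernel's temporal span (33) exceeds T = 29; zero padding makes this benign.

## Fusion and head

The three branch outputs are concatenated per time step (29×384), passed
through dropout (0.1) and layer norm, positionally re-encoded, and encoded
by N_m = 4 further layers at width 384 (kept at 3×128 rather than
re-projected — the minimal choice that preserves each channel's features).
The classifier head is temporal mean pooling followed by a single affine map
to five logits and a softmax; argmax ties break toward the lowest stage
index (W first). Ablation flags reduce the network to its baseline:
`use_ccte=False` swaps causal projections for plain affine Q/K/V and turns
CrossNorm off (the basic-transformer baseline); `use_mfem=False` removes the
multi-scale block. Parameter counts order as BL < BL+MFEM < full and
BL < BL+CCTE ≤ full.

## Training and evaluation

Cross-entropy, AdamW (lr 5e-5, decoupled weight decay 0.01, β = 0.9/0.999),
batch size 32, at most 100 epochs with early stopping when validation
accuracy has not improved for 10 epochs; the best-validation weights are
restored. No class reweighting is applied — N1 weakness is a known property
of this model family and is reported, not patched. Cross-validation is
subject-wise (a subject appears in exactly one of train/validation/test per
fold; epoch-wise splitting would leak within-night correlations); within a
fold, ~1/k of the training subjects (at least one) rotate into the
validation role. Every stochastic element — initialization, batch order,
dropout, CrossNorm pairing — derives from one seed, making runs
bit-reproducible on a single device.

Metrics: accuracy = trace/total of the 5×5 confusion matrix (rows = actual),
per-class precision/recall/F1 with zero denominators scored 0 under a
warning, MF1 = unweighted mean of the five F1 values, and Cohen's
κ = (p_o − p_e)/(1 − p_e) with p_e from the row/column marginals. Values are
kept at full precision internally and displayed with half-up rounding to one
decimal, κ on the ×100 scale — the convention of published staging tables.
The shipped benchmark confusion matrices validate the suite end to end;
their Sleep-EDF-20 and OSA-cohort summary values are reproduced exactly at
printed precision. (For Sleep-EDF-78 and SHHS the published summary rows are
not perfectly consistent with their own printed matrices; the suite reports
what the counts imply.)

## The implementation substrate

No GPU framework is used: the network runs on a small reverse-mode autodiff
engine over float64 NumPy arrays written for this package (broadcast-aware
arithmetic, batched matmul, fused layer-norm/softmax/cross-entropy, causal
1-D and dilated 2-D convolutions as custom ops with exact adjoints). Every
op's gradient is tested against central finite differences at 1e-6
tolerance. This keeps the full pipeline dependency-light, deterministic and
CPU-sized; the cost is that full-scale (N_s=8, width-128/384) training is
slow, which is why experiments use the reduced configuration below.

## Synthetic data generator

The generator emulates the statistical structure the model relies on, not
biophysics. Stage sequences come from a first-order Markov chain
parameterized as P = s·I + (1−s)·1πᵀ, whose stationary distribution is
exactly the target occupancy π. Defaults: π = (W 6, N1 4, N2 48, N3 20,
REM 22)%, matching standard sleep architecture (N1 2–5%, N2 45–55%, N3
15–25%, REM 20–25%), persistence s = 0.9 (≈7 stage changes per 100 epochs).
OSA mode doubles the off-diagonal mass (s = 0.8) and triples N1 at the
expense of N3 and REM: π = (16, 12, 50, 10, 12)% — the fragmentation
signature of apnea. These OSA parameters are surrogates chosen to reproduce
the qualitative clinical picture; they are not calibrated to any cohort.

Signals are built per epoch from band-passed white noise (301-tap FIR,
1/f-flavored band weighting), rescaled to a stage RMS in µV (W 15, N1 20,
N2 25, N3 40, REM 20), with Hann-windowed sinusoid bursts for N2 spindles
(14 Hz, 1 s, ≈4/epoch) and K-complex surrogates (1 Hz, ≈1/epoch). The EOG
surrogate is <1.5 Hz low-passed noise at a stage-dependent RMS (large for
REM and wake, small in NREM) plus 20% EEG crosstalk. Two EEG channels are
independent draws from the same template. EDF output uses 16-bit encoding
with ±250 µV physical range for EEG and ±500 µV for EOG (REM deflections
exceed 250 µV), and the hypnogram sidecar uses Sleep-EDF's annotation
dialect ("Sleep stage W/1/2/3/R").

What the generator does **not** emulate: real EEG nonstationarity within a
stage, artifacts (movement, electrode pop, sweat), inter-subject variability
beyond the seed, age effects, apnea events themselves (no SpO₂/airflow), or
ambiguous transitional epochs. Consequently the synthetic stages are almost
perfectly separable (nearest-centroid accuracy on band powers ≈100%), and a
passing learning check demonstrates that the architecture, gradients,
optimizer and pipeline are correct — not that the model reaches clinical
accuracy on real PSG.

## Scaled-down experiment sizes

The learning check trains a reduced model — encoder width 32 (with an affine
128→32 input projection per channel), N_s = 2, N_m = 1, the loss/optimizer/
learning-rate defaults unchanged — on 1000 balanced synthetic epochs (200
per stage) with 125 validation and 125 held-out epochs, for at most 20
epochs. It reaches ≈97% held-out accuracy (chance 20%) in a few minutes on
one CPU. Full-size training on real cohorts is out of scope for the test
suite; the configuration knobs (H, N_s, N_m, dilation schedule, ablation
flags) expose the full architecture.

## Known limitations

- Single-epoch classification only; no multi-epoch sequence context.
- The metric suite's display rounding is half-up; published tables mix
  rounding conventions, so only rounding-stable comparisons are meaningful.
- The EDF writer covers the generator's needs (16-bit EDF, EDF+C annotation
  sidecar), not the full EDF+ specification (no discontinuous files, no
  per-channel rates).
- CrossNorm pairing is batch-global; with very small batches the exchange
  degenerates toward identity (a batch of 1 pairs with itself).
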
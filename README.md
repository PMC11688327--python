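# somnostage

Automatic sleep staging from multimodal polysomnography (PSG): two EEG
channels and one EOG channel are turned into time-frequency images and
classified into the five AASM stages (W, N1, N2, N3, REM), one label per
30-second epoch. The package is aimed at sleep-research groups who want a
fully inspectable, CPU-trainable reference implementation of a
spectrogram-transformer staging architecture — including the fragmented-sleep
regime of obstructive sleep apnea (OSA) — plus a synthetic PSG generator so
every pipeline stage is exercisable without clinical data.

## The model

Each 30-s, 100 Hz epoch channel is mapped to a log-scaled, standardized
spectrogram **S** ∈ ℝ^(T×F) with T = 29 frames and F = 128 bins (2-s Hamming
window, 50% overlap, 256-point FFT, DC bin dropped). Per channel, the image
is treated as a sequence of T tokens of F features and encoded by a stack of
N_s = 8 attention layers in which the query/key/value projections are
**causal convolutions** — token *t*'s projection sees only tokens ≤ *t*, so
the encoder respects the temporal order of stage transitions:

    Attention(Q̂, K̂, V̂) = softmax(Q̂K̂ᵀ / √d_head) V̂,   Q̂ = CausalConv(X), …

with H = 8 heads concatenated, a 150-unit position-wise feed-forward network,
and residual connections followed by normalization. During training the
normalization is augmented by **CrossNorm**: feature-wise means and standard
deviations are exchanged between randomly paired batch instances, widening
the style distribution the encoder sees (evaluation uses plain layer norm).

The encoder output passes through a **multi-scale feature-extraction module**:
a cascade of 3×3 dilated convolutions at rates [1, 4, 8, 16]
(X₁ = conv₁(x), Xᵢ = convᵣᵢ(x + Xᵢ₋₁)) whose branch maps are fused by
global-average-pooled, sigmoid-then-softmax weights per frequency position
and added back to the input. The three channel branches are concatenated
along the feature axis (29 × 384), layer-normalized, encoded by N_m = 4
further attention layers, mean-pooled over time and mapped to five stage
probabilities. Training uses cross-entropy with AdamW at lr 5·10⁻⁵, early
stopping on validation accuracy, and subject-wise K-fold cross-validation.
Evaluation reports accuracy, macro-F1 (MF1 = Σ F1_c / 5) and Cohen's κ.

Everything — including a small reverse-mode autodiff engine the network and
its training loop run on — is NumPy, so a reduced configuration trains in
minutes on one CPU.

## Worked example

Recompute benchmark metrics from shipped confusion matrices
(`python examples/04_metrics_from_confusion.py`):

```
dataset           ACC    MF1  kappa
sleep_edf_20     88.7   83.5   84.6
sleep_edf_78     86.0   82.5   80.7
shhs             86.1   80.8   81.5
osa_clinical     80.4   78.1   72.6
```

ACC is the diagonal fraction of the 5×5 confusion matrix, MF1 the unweighted
mean of per-stage F1 scores, κ the chance-corrected agreement (×100). The
OSA cohort is hardest — fragmented sleep inflates N1, the stage every model
confuses most.

Generate synthetic nights and see the OSA fragmentation signature
(`python examples/01_generate_synthetic_cohort.py`):

```
healthy seed=0: W 3.0%, N1 8.8%, N2 50.7%, N3 9.8%, REM 27.8% | 24 stage transitions
OSA     seed=0: W 14.0%, N1 18.5%, N2 41.5%, N3 13.0%, REM 13.0% | 57 stage transitions
```

`examples/02_spectrogram_images.py` shows each stage's spectral peak landing
in its defining band (N3 → 3.1 Hz delta, W → 9.0 Hz alpha, …), and
`examples/03_train_reduced_model.py` trains a reduced model end to end in a
couple of minutes and prints its held-out confusion matrix and summary
(a 12-epoch run on 480 training epochs lands around
`ACC 81.7%  MF1 80.0%  kappa 76.9`; the longer acceptance-scale run
reaches ≈97%).

The same stages are available as a shell pipeline:

```bash
somnostage simulate --n-subjects 3 --epochs 200 --seed 0 --out cohort/
somnostage ingest --edf cohort/subject00.edf --ann cohort/subject00-Hypnogram.edf --out s0.npz
somnostage transform --in s0.npz --out s0-img.npz
somnostage metrics --confusion-csv my_confusion.csv
```

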
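# Methods

## Model

### Image track (TVSFE)

Preprocessing follows the exam format: the printed template and background
are near-gray, the pen ink is saturated.  Denoising applies a 3×3 mean filter
then a 3×3 median filter per channel (edge replication); the order —
smoothing before the edge-preserving median — and the kernel size are
configurable, since nothing in the format forces a particular choice.
Grayscale suppression whitens a pixel iff all three pairwise channel
differences are *strictly* below 45; the predicate is idempotent, and the
count of suppressed pixels is monotone in the threshold.  Suppression keeps
the saturated pen trace and removes the template — the informative signal is
the trace, so the near-gray content is what gets whitened.  Images are then
bilinearly resized to 512×512 and scaled to [0, 1]; they enter the network as
3 channels (the pen hue survives suppression and is informative, so collapsing
to grayscale would discard it).

Convolutions use replicate (edge) padding rather than zero padding: the
canvas background is white, and zero padding would wrap every feature map in
an artificial dark frame that filters respond to more strongly than to the
pen trace itself — in early experiments most of the top Grad-CAM mass sat on
that border ring, and replicate padding removes the artifact at the source.

The CNN: a 7×7 stem convolution with stride 2, batch norm, ReLU, and a 2×2
max pool (the stem stride and pool bring 512×512 inputs to a tractable map
before the attention stages); then four CDAB stages of widths 32→64→128→256
with strides (1, 2, 2, 2), coordinate attention + squeeze-and-excite in the
first two stages and triplet attention in the last two.  Each CDAB block is
ghost convolution → attention → batch norm, summed with a residual that is
the identity when shapes match and a strided 1×1 projection otherwise, then
ReLU.  The ghost module produces `out/ratio` channels with a dense 3×3
convolution and the rest with cheap depthwise 3×3 maps (ratio 2 by default),
which is strictly cheaper in parameters than a dense 3×3 convolution at every
tested width.  Attention reductions default to 8; the triplet-attention gate
convolution is 7×7, the standard size for that mechanism.

Global average pooling feeds a dense head (hidden width 2048, LeakyReLU
slope 0.01) that outputs a 256-dim embedding, which is layer-normalised and
L2-normalised.  The head width was chosen so the default model lands at
~1.31 M trainable parameters, in the low-millions band the architecture is
designed for.  The unit embedding is amplitude-embedded into 8 qubits
(2⁸ = 256 — the config validates this identity), passed through depth-2
strongly entangling layers, and read out as 8 Pauli-Z expectations.

### Circuit simulation

States are complex vectors of length 2ⁿ stored as real/imaginary parts on
the autodiff tape.  Convention: **qubit 0 is the most significant bit** of
the basis index; this fixes amplitude ordering and is asserted by the oracle
tests.  A strongly entangling layer applies `RZ(a)`, `RY(b)`, `RZ(c)` per
qubit followed by a ring of CNOTs with control `q` → target `(q + r_l) mod n`
and per-layer range `r_l = (l mod (n−1)) + 1`; the CNOT ring is compiled to a
single basis permutation per layer.  Simulation is exact — no shot noise —
and expectations are computed from the probability vector.  Circuit depths
default to 2 (image track) and 4 (tabular track); both are configuration
knobs, as the parameter budget alone does not determine them.  Gradients are
ordinary reverse-mode autodiff through the statevector; the test suite checks
them against central finite differences (1e-5) and the amplitudes against an
independent dense Kronecker-product simulator (1e-10 over 100 random circuits
with n ≤ 4).

### Structured track and fusion

The six features (gender, handedness mapped to {0, 1}; age, rms, mrt,
std_diff) are imputed (numeric → mean, categorical → mode) and min–max
mapped onto [0, π] — `x' = π(x − min)/(max − min)`, constant features map to
0 — with statistics fitted on the training split only; held-out values
outside the fitted range are clipped so the RY encoding's domain stays valid.
The track is `RY` encoding → entangling layers → 6 Pauli-Z expectations.
Fusion layer-normalises each track's readout, concatenates (8 + 6 = 14),
and applies dense layers of widths (64, 32) → 2 logits → softmax.

All three ablations are configuration switches, not code forks:
`use_tabular_track=False` (image only), `use_image_track=False` (tabular
only), and `quantum=False`, which swaps the image circuit for a 256→8 linear
readout and the tabular circuit for a small ReLU MLP of the same output
width.

## Training and evaluation

Focal loss `−α(1−p_t)^γ log p_t` with γ = 3 and α = 1 (an
inverse-class-frequency option exists for imbalanced data); Adam at 1e-4;
batch size 4; ReduceLROnPlateau with factor 0.5 and patience 3; early
stopping with patience 10; the best-validation-loss weights are restored.
Metrics are accuracy and macro-averaged precision/recall/F1 plus the
confusion matrix.  Cross-validation is stratified 5-fold, grouped by patient
by default so no subject's exams span folds (an ungrouped mode exists);
imputation and scaling are refitted inside each fold on its training part.
The bootstrap CI resamples the pooled per-sample fold predictions with
replacement 10,000 times and takes percentile bounds at 95%.

## Synthetic exam generator

The generator emulates the exam format, not handwriting biomechanics.
Templates are an Archimedean spiral `r = a + bθ` (3 turns, sampled at 400
points/turn) or a square-wave meander sweeping the canvas; both are centred
on a 512-px white canvas and stroked 3 px wide with anti-aliasing off, so the
suppression predicate behaves crisply.  The template ink is near-gray
(110, 110, 110) and the pen saturated blue (30, 30, 200); the generator
rejects colors that would break the suppression contract.  A subject trace
displaces each template point along the local curve normal by
`A·sin(2π·f·s) + N(0, σ²)` with `s` the normalised arc length: a sinusoid is
the simplest model that produces the loop-irregularity pattern saliency
analysis should find.  Defaults: patients A = 6 px, f = 30 cycles per trace
(≈ 4–6 per spiral revolution, matching the 4–6 Hz resting-tremor band at
plausible drawing speeds), σ = 1 px; controls A = 0, σ = 0.75 px (pen jitter
only).  Zero tremor reproduces the template exactly, giving
RMS = MRT = std_diff = 0.

Derived features use the point-wise Euclidean deviations `d_i`:
`RMS = √(mean d²)`, `std_diff = std(d)`, and `MRT = mean |d_{i+1} − d_i|` —
MRT has no published formula, and the mean absolute first difference is used
as a stand-in because it captures oscillation rather than magnitude,
complementing RMS.  Point correspondence is by construction (same index),
which sidesteps the template-alignment problem real exams have.  Ages are
truncated normals per class (controls 44.22 ± 16.53, patients 58.75 ± 7.51,
clipped to [18, 90] years) and sex ratios follow the cohort the format comes
from; both therefore carry class signal, which matters for sensitivity
analysis (below).

What passing tests on this generator do **not** show: robustness to template
misalignment, pen-pressure or speed effects, scanner artifacts, or the much
weaker tremor amplitudes of early-stage disease.  The synthetic signal is
deliberately strong; desk-scale results say the pipeline recovers a planted
signal, not that it reaches any particular accuracy on clinical data.

## Explainability

Grad-CAM: channel weights are the spatial mean of ∂(class logit)/∂(activation)
at a chosen stage; the map is `ReLU(Σ_k w_k A_k)`, bilinearly upsampled to
the input size and min–max normalised (an all-zero map stays zero).  The
default layer is the last CDAB stage (highest-level features).  Each probe
exam in the trace-localisation check is fed its own derived features
(computed from its simulated traces and normalised with the training run's
fitted pipeline), since saliency explains a model's decision for a coherent
sample, not for an image paired with foreign covariates.

Structured-feature sensitivity perturbs one column at a time — permutation by
default (preserves marginals), or Gaussian noise with the column's standard
deviation — and scores each feature by the mean accuracy drop over repeats
(negative drops clip to 0); probability-shift scoring is available as an
option.  In the full generator cohort several columns carry redundant signal
(rms/mrt/std_diff are correlated and age is class-conditional), so permuting
any single column need not move accuracy at all; the recovery check therefore
plants a *single*-signal cohort by permuting every feature column except RMS
across samples, destroying all other class associations while preserving
marginals, and verifies RMS ranks first.  Those trials train the
tabular-only model with plain cross-entropy (γ = 0; the cohort is balanced,
so focal re-weighting is unnecessary) at a larger batch and learning rate —
the quantum feature map trains stably at far higher rates than the CNN.

## Numerical choices and desk-scale sizes

float32 for network weights and training; float64 in the oracle tests.
Softmax and log-softmax are computed shift-stabilised; `log p_t` is clamped
at 1e-8; the embedding's L2 norm at 1e-12.  Batch-norm eps 1e-5, momentum
0.1.  He initialisation for convolutions, Glorot for dense layers, circuit
angles uniform in ±0.1π.  The desk-scale configuration — 40 + 40 subjects ×
4 draws, 128×128 inputs, stem width 16, two CDAB stages (16, 32), head width
128 — was sized so a full train/evaluate cycle takes a few minutes on one
CPU core while keeping every architectural mechanism (both circuits, both
attention variants, ghost convolutions, residuals) exercised.

## Known limitations

The MRT definition is a documented stand-in.  The published architecture
does not pin down the stage plan, circuit depths or head widths; the defaults
here are one consistent instantiation whose total parameter count lands in
the intended band, and all of them are config keys.  The simulator is exact
and noiseless, so nothing here speaks to behaviour on physical quantum
hardware.  Training on real HandPD data is supported through the dataset
readers but requires the dataset to be downloaded separately.
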
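# Methods

## Problem and model

The package segments the femoral intercondylar notch — the concave
groove between the femoral condyles — in single-channel 2D knee slices,
and a five-class knee variant (background, femur, tibia, meniscus,
cruciate ligament). The network is a U-shaped encoder–decoder whose
skip pathway is frequency-aware: the claim embodied in the architecture
is that notch boundaries live in the high-frequency image content that
plain strided encoders discard, and that explicitly separating,
denoising and re-fusing that content — while attending to saliency-
uncertain pixels — yields more faithful boundaries than a generic
encoder–decoder.

### Encoder layout

Four backbone stages at /1, /2, /4 and /8 of the input resolution plus
a fifth stride-2 projection to a /16 bottleneck. Two families are
provided: a residual CNN (stem + one residual block per stage) and a
hierarchical window transformer (space-to-depth patch merging + single-
head window attention with pre-norm MLP, window 4, falling back to
smaller windows when the grid does not divide). Putting stage 1 at full
resolution gives the dense detail extractor an undegraded signal and
gives every wavelet block a natural half-resolution partner feature
(stages 2–4 pair with stages 3, 4 and the bottleneck); the total
downsampling factor is still 16, hence the input-divisibility rule.

### Wavelet split and fusion

The transform is the orthonormal single-level 2D Haar analysis: for a
2×2 block [[a, b], [c, d]],

    ll = (a+b+c+d)/2   lh = (a+b−c−d)/2   hl = (a−b+c−d)/2   hh = (a−b−c+d)/2

`lh` responds to variation across rows (horizontal edges), `hl` across
columns, `hh` diagonally. The orthonormal normalisation was chosen over
the unnormalised filter pair because it preserves energy (Parseval),
which gives the analysis step a sharp test surface (identity and energy
checks to 1e−6/1e−5); the band-to-axis assignment is fixed by the
worked 2×2 example and cross-checked against PyWavelets. Odd spatial
sizes are reflect-padded by one trailing pixel and cropped after
synthesis. Detail bands pass through the shrinkage operator
`sign(v)·max(|v|−t, 0)` with t = 0.05, applied to features at roughly
unit scale (post batch-norm); the threshold is exposed in config. The
thresholding precedes the learnable convolutions, matching the order
split → denoise → concatenate → convolve. The high-frequency path output
sits at half the pre-wavelet resolution (a quarter of its area); any
remaining mismatch in the fusion step is closed by integer average
pooling, never by upsampling the details.

### Multi-scale depth-wise blocks

The parallel block sums depth-wise branches with kernels (3, 5, 7) and
mixes them with a pointwise convolution inside a residual; summation
(not concatenation) keeps the block lightweight. The serial bottleneck
expands pointwise by 2×, chains depth-wise kernels (7, 9) — theoretical
receptive field 1 + Σ(k−1) = 15, verified by a gradient-footprint probe
— and projects back inside a residual. Kernel sizes, expansion and
layer counts are config parameters; the defaults are small because
nothing in the method requires wide layers to be expressed.

### Uncertainty attention

A sigmoid saliency map F_m (values in [0, 1], produced by the 1×1
deep-supervision head of the preceding decoder stage; the bottleneck
carries its own head to seed the deepest gate) is decomposed at
threshold 0.5 into m_f = max(F_m−0.5, 0), m_b = max(0.5−F_m, 0) and
m_u = 0.5−|F_m−0.5|. The identities m_f+m_b+m_u = 0.5 and m_f·m_b = 0
hold pointwise and are enforced by tests. The uncertainty map is added
to the bilinearly upsampled saliency, concatenated with the decoder
feature, projected by three 1×1 convolutions to Q, K, V, and single-
head scaled dot-product attention (row-softmax of QᵀK/√d) re-weights V;
a residual from the decoder feature stabilises early training. The
threshold is fixed at 0.5 by default and exposed in config. When the
token count exceeds `attention_resolution_cap` (default 4096), K and V
are average-pooled by powers of two down to the cap — a documented
memory contract, never an error — while the query grid and output
resolution are unchanged.

### Toggles and the ablation grid

Each component can be disabled, in which case it is replaced by a
parameter-free identity (never a convolutional stand-in), so enabling
any module strictly increases the parameter count and all sixteen
combinations build. `ablation_grid` enumerates the six incremental
rows per backbone family: baseline, +detail, +wavelet, +detail+wavelet,
+multi-scale, +attention. With the wavelet blocks off but the detail
extractor on, pooled detail features are injected into the skips
through a 1×1 convolution so the detail branch stays live on its own.

## Loss

`Loss = α·Dice + β·Focal` with α = β = 0.5 by default (the weighting is
exposed; equal weights are the neutral choice absent a stated value).
Dice is the soft (probability-valued) form 1 − 2Σpy/(Σp+Σy) — sums of
products replace set intersections so the loss is differentiable — with
the 0/0 case defined as 0 (perfect absence), averaged over
non-background classes in the multiclass task. Focal is
−(1/N)·Σ α_k (1−P)^γ log(P+ε) evaluated at each pixel's true class
(one-hot convention: wrong-class probabilities enter only through the
softmax coupling), with γ = 2 and ε = 1e−5 guarding log(0).
Class weights α_k default to inverse pixel frequency normalised to
mean 1; classes absent from the training masks receive the largest
observed weight. Deep supervision adds soft-Dice terms between each
stage's saliency map and the block-averaged foreground indicator at
that resolution, weighted 0.4/0.3/0.2/0.1 from deep to shallow.

## Metrics

DSC = 2TP/(2TP+FN+FP) and IoU = TP/(TP+FN+FP) from exact confusion
counts (they satisfy IoU = DSC/(2−DSC)); the all-empty case scores 1.
Boundaries are foreground pixels with a background 4-neighbour, the
image border counting as background; pixel centres are scaled by the
pixel spacing and distances are Euclidean. HD95 takes the 95th
percentile (linear interpolation) of the pooled bidirectional
nearest-distance multiset; the alternative max-of-directed-percentiles
reading is available behind a flag, pooled being the default because it
matches common medical-segmentation tooling. ASSD is the symmetric
nearest-distance mean. Empty boundary sets make the distance metrics
undefined and they are reported as missing, never as 0. Multiclass
reports are one binary report per foreground class plus their mean.

## Training procedure

AdamW with weight decay 1e−4; learning rate cosine-annealed from 1e−4
to 1e−6 with period 1000 epochs, re-starting (warm restart) beyond one
period. Early stopping monitors epoch-wise validation DSC (foreground
class, or class mean for multiclass) with patience 20 and restores the
best-scoring parameters. Augmentation applies random rotation (±15°),
horizontal flip (p = 0.5) and elastic deformation (α = 800, σ = 20),
with nearest-neighbour resampling of masks so no new label can appear.
Five-fold cross-validation uses a seeded shuffled split; every run
writes its resolved YAML config, per-epoch CSV log and best checkpoint.

The implementation runs on the package's own reverse-mode autodiff
engine over float64 NumPy arrays (`notchseg.tensor`), with convolution
via im2col/BLAS and hand-written backward rules, all verified against
central finite differences. Double precision keeps the oracle-based
test tolerances (1e−5 … 1e−12) meaningful.

## The phantom generator

The generator emulates the statistical structure that makes the notch
hard: a bright femur-like ellipse (horizontal extent drawn
U(48, 52) mm) whose shaft leaves the frame top; a notch cut from its
distal end with full width drawn U(5, 8) mm, arch depth U(26, 34) mm
and one of three arch templates (superellipse exponents 1.2 / 2 / 3,
the third with a central ridge — an a/u/w-shaped morphology range);
a near-isointense distractor blob just distal to the opening, offset
from the notch signal by exactly `distractor_contrast` (default 0.05,
emulating sub-10% signal differences); Gaussian boundary blur
(σ = 1.5 px) and additive Gaussian noise (σ = 0.02), clipped to [0, 1];
and, with probability 0.3, an osteophyte-like bony disc (radius
1–3 mm) eating into the notch contour. The default frame is 104 px at
0.5 mm/px. With these defaults the population means over 200 seeds land
inside the anatomical bands the generator is built around — mean notch
width in [5, 8] mm, mean notch area fraction in [5, 8]% of pixels, mean
femur extent ≈ 50 mm — which `scripts/acceptance.py` recomputes from
scratch. The depth range and opening-row fraction were fixed once
against those bands and are module constants, not tuning knobs.

What the phantom does **not** model: MRI physics (no k-space, bias
fields, partial-volume or anisotropic voxels), 3D continuity between
slices, realistic bone texture, or population shape statistics. Passing
tests therefore demonstrate that the architecture, losses, metrics and
pipeline are correct and trainable end to end — not that the method
reaches any particular accuracy on clinical MRI.

## Problem sizes in the test suite

Tests exercise the network at 32–64 px with stage widths (4–32
channels); the end-to-end trainability check overfits eight 64 px
phantoms with stage widths (8, 16, 24, 32), learning rate 3e−3 and at
most 200 epochs, stopping once training DSC exceeds 0.955. These sizes
are the package's CPU-scale defaults for its test fixtures; the
configs scale to clinical 256 px slices unchanged.

## Known limitations

* Single-head attention without positional encoding; multi-level
  wavelet pyramids and non-Haar families are out of scope by design.
* Batch normalisation statistics make training-mode outputs batch-
  dependent; determinism guarantees apply to eval mode and to fixed
  seeds on one machine.
* The transformer backbone is a compact structural analogue of
  hierarchical window-attention encoders, not a pretrained model;
  no pretrained weights are loaded anywhere.
* Boundary metrics use pixel-centre point sets (no sub-pixel surface
  model), appropriate for 2D slices.
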
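# notchseg

Segmentation of the **femoral intercondylar notch** in 2D knee MRI
slices with a wavelet multi-scale contextual attention network — plus a
seeded synthetic phantom generator so the entire method can be built,
trained and evaluated on one CPU without any MRI data.

The intercondylar notch (fossa) is the concave groove at the distal
femur that houses the cruciate ligaments. Delineating it matters for ACL
reconstruction planning and knee-disease assessment, but it is hard to
segment automatically: the structure is narrow (5–8 mm) inside a ~50 mm
femoral mass, scar-like tissue nearby can differ from it by less than
10% in signal, roughly 30% of patients carry osteophytes that deform its
contour, and the bone–ligament interface blurs in MRI.

## The model

A U-shaped encoder–decoder (residual-CNN or window-transformer backbone)
augmented with four components:

* **Dense detail extraction** — densely connected separable convolutions
  at the full-resolution stage retain the high-frequency structure that
  downsampling destroys.
* **Wavelet split-and-fusion** — each stage feature is decomposed by an
  orthonormal single-level Haar transform into the approximation LL and
  detail bands LH/HL/HH; details are soft-thresholded
  (`sign(v)·max(|v|−t, 0)`, t = 0.05) to suppress noise, processed by a
  convolutional high-frequency path, and fused with LL plus the deeper
  encoder feature into frequency-aware skip connections.
* **Multi-scale depth-wise convolution** — parallel depth-wise branches
  (kernels 3/5/7) in the decoder and a serial large-kernel bottleneck
  (kernels 7, 9; receptive field 1 + Σ(k−1) = 15) to cover the scale
  range from notch to condyles.
* **Uncertainty attention** — a sigmoid saliency map F_m from the deeper
  decoder stage is decomposed at threshold 0.5 into foreground
  `m_f = max(F_m−0.5, 0)`, background `m_b = max(0.5−F_m, 0)` and
  uncertainty `m_u = 0.5−|F_m−0.5|`; scaled dot-product attention over
  Q/K/V projections of the m_u-enhanced feature propagates semantics
  from confident anatomy into the uncertain boundary band.

Training minimises `α·DiceLoss + β·FocalLoss` with inverse-frequency
class weights and deep supervision, using AdamW (weight decay 1e-4),
cosine-annealed learning rate and early stopping on validation DSC.
Evaluation reports DSC, IoU, 95th-percentile Hausdorff distance and
average symmetric surface distance in millimetres.

The whole network runs on a small reverse-mode autodiff engine over
NumPy (`notchseg.tensor` / `notchseg.nn`), which keeps the package
dependency-light and every test CPU-sized.

## Worked example

```python
import numpy as np
from notchseg import NotchSegmenter, PhantomConfig, generate_notch_phantom, measure_phantom

# eight seeded 64x64 phantoms (1 mm pixels keep the 50 mm femur in frame)
cfg = PhantomConfig(image_size_px=64, pixel_spacing_mm=1.0)
samples = [generate_notch_phantom(cfg, seed) for seed in range(1, 9)]
X = np.stack([s.image for s in samples])
y = np.stack([s.mask for s in samples])

seg = NotchSegmenter(stage_channels=(8, 16, 24, 32), detail_channels=16,
                     attention_resolution_cap=256, lr_initial=3e-3,
                     max_epochs=80, seed=0)
seg.fit(X, y)
print(f"train DSC {seg.score(X, y):.3f}")

rep = measure_phantom(generate_notch_phantom(PhantomConfig(), seed=1))
print(f"notch width {rep.notch_width_mm:.1f} mm, "
      f"area fraction {100 * rep.notch_area_fraction:.1f}%")
```

Output:

```
train DSC 0.980
notch width 6.0 mm, area fraction 5.5%
```

The DSC of 0.98 shows the full model overfitting eight phantoms end to
end — the architecture, loss and optimiser are all live. The geometry
line confirms one default-config phantom: a 6.0 mm-wide notch covering
5.5% of the slice, inside the anatomical bands the generator emulates.

A command line covers the same pipeline:
`notchseg make-phantoms | train | crossval | predict | evaluate`
(all subcommands accept `--seed` and write their resolved YAML config).

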
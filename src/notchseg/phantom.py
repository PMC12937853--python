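"""Seeded synthetic knee-slice phantoms.

The generator emulates the imaging situation that makes the femoral
intercondylar notch hard to segment, without requiring any MRI data:

* a bright femur-like mass (~50 mm across) filling most of the frame,
  its shaft running out of the top of the field of view;
* a narrow concave notch (5-8 mm wide) cut into its distal end, drawn
  from one of three arch templates (a/u/w shaped) so that notch
  morphology varies between samples;
* a near-isointense distractor blob just distal to the notch opening,
  within `distractor_contrast` of the notch signal (scar-like tissue
  with < 10% signal difference);
* Gaussian boundary blur and additive Gaussian noise;
* with probability `osteophyte_probability`, a bony protrusion (1-3 mm
  radius) deforming the notch contour.

A five-class variant (background / femur / tibia / meniscus / cruciate
ligament) supports the multi-structure knee task.  Identical
(config, seed) pairs produce bit-identical samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

# default geometry constants (frozen; see docs/methods.md)
_NOTCH_DEPTH_MM_RANGE = (26.0, 34.0)   # arch depth above the opening row
_OPENING_FRACTION = 0.70               # opening row at cy + 0.70 * b
_CENTER_ROW_FRACTION = 0.40            # femur centre row / image size
_ARCH_TEMPLATES = ("a", "u", "w")      # superellipse exponents 1.2 / 2 / 3


class PhantomConfigError(ValueError):
    """A phantom configuration violated one of its invariants."""


@dataclass
class PhantomConfig:
    image_size_px: int = 104
    pixel_spacing_mm: float = 0.5
    notch_width_mm_range: tuple = (5.0, 8.0)
    femur_diameter_mm: float = 50.0
    boundary_blur_sigma_px: float = 1.5
    noise_sd: float = 0.02
    distractor_contrast: float = 0.05
    osteophyte_probability: float = 0.3
    n_classes: int = 2
    notch_intensity: float = 0.35
    femur_intensity: float = 0.85
    background_intensity: float = 0.12

    def __post_init__(self):
        lo, hi = self.notch_width_mm_range
        if not (0 < lo <= hi):
            raise PhantomConfigError(
                "notch_width_mm_range must satisfy 0 < lower <= upper, "
                f"got {self.notch_width_mm_range}"
            )
        if self.femur_diameter_mm < hi:
            raise PhantomConfigError(
                "femur_diameter_mm must be at least the notch width upper "
                f"bound ({hi} mm), got {self.femur_diameter_mm}"
            )
        if self.image_size_px * self.pixel_spacing_mm < self.femur_diameter_mm:
            raise PhantomConfigError(
                "the femur does not fit in frame: image_size_px * "
                f"pixel_spacing_mm = "
                f"{self.image_size_px * self.pixel_spacing_mm} mm < "
                f"femur_diameter_mm = {self.femur_diameter_mm} mm"
            )
        if self.image_size_px < 1 or self.pixel_spacing_mm <= 0:
            raise PhantomConfigError("image size and pixel spacing must be positive")
        if self.boundary_blur_sigma_px < 0 or self.noise_sd < 0:
            raise PhantomConfigError("blur sigma and noise sd must be nonnegative")
        if not 0.0 <= self.distractor_contrast <= 0.1:
            raise PhantomConfigError(
                f"distractor_contrast must lie in [0, 0.1], got "
                f"{self.distractor_contrast}"
            )
        if not 0.0 <= self.osteophyte_probability <= 1.0:
            raise PhantomConfigError("osteophyte_probability must lie in [0, 1]")
        if self.n_classes not in (2, 5):
            raise PhantomConfigError(
                f"n_classes must be 2 (notch) or 5 (knee), got {self.n_classes}"
            )


@dataclass
class ImageSample:
    image: np.ndarray          # float64 in [0, 1]
    mask: np.ndarray           # integer labels
    pixel_spacing_mm: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape} and mask {self.mask.shape} "
                "must share a spatial shape"
            )


@dataclass
class PhantomGeometryReport:
    notch_width_mm: float
    notch_area_fraction: float
    femur_diameter_mm: float
    has_osteophyte: bool


def _superellipse(dy, dx, ry, rx, p):
    return (np.abs(dx) / rx) ** p + (np.abs(dy) / ry) ** p <= 1.0


def generate_notch_phantom(config: PhantomConfig, seed: int) -> ImageSample:
    """Binary notch phantom: label 1 marks the intercondylar notch."""
    if config.n_classes != 2:
        raise PhantomConfigError(
            f"the notch phantom is binary; config has n_classes={config.n_classes}"
        )
    rng = np.random.default_rng(seed)
    n = config.image_size_px
    s = config.pixel_spacing_mm
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)

    # femur: bright ellipse, shaft exiting through the top of the frame
    d_mm = rng.uniform(config.femur_diameter_mm - 2.0, config.femur_diameter_mm + 2.0)
    d_mm = min(d_mm, n * s)
    a = d_mm / s / 2.0                     # horizontal semi-axis, px
    b = a * rng.uniform(0.95, 1.05)        # vertical semi-axis, px
    cy = _CENTER_ROW_FRACTION * n + rng.uniform(-2, 2)
    cx = (n - 1) / 2.0 + rng.uniform(-1.5, 1.5)
    cx = float(np.clip(cx, a, n - 1 - a))  # full width stays in frame
    femur = _superellipse(yy - cy, xx - cx, b, a, 2.0)

    # notch: arch template + opening channel, cut from the distal femur
    w_mm = rng.uniform(*config.notch_width_mm_range)
    w = w_mm / s                           # full width, px
    depth = rng.uniform(*_NOTCH_DEPTH_MM_RANGE) / s
    template = _ARCH_TEMPLATES[rng.integers(len(_ARCH_TEMPLATES))]
    p_exp = {"a": 1.2, "u": 2.0, "w": 3.0}[template]
    ncx = cx + rng.uniform(-3, 3)
    y_open = cy + _OPENING_FRACTION * b
    arch = _superellipse(y_open - yy, xx - ncx, depth, w / 2.0, p_exp)
    arch &= yy <= y_open
    channel = (np.abs(xx - ncx) <= w / 2.0) & (yy > y_open)
    notch = (arch | channel) & femur
    if template == "w":
        ridge = (np.abs(xx - ncx) <= w / 6.0) & (
            yy <= y_open - 0.72 * depth
        )
        notch &= ~ridge

    # osteophyte: small bony disc eating into the notch contour
    has_osteo = bool(rng.random() < config.osteophyte_probability)
    osteo = np.zeros_like(femur)
    if has_osteo:
        side = rng.choice([-1.0, 1.0])
        oy = y_open - rng.uniform(0.15, 0.55) * depth
        ox = ncx + side * w / 2.0
        r_px = rng.uniform(1.0, 3.0) / s
        osteo = (yy - oy) ** 2 + (xx - ox) ** 2 <= r_px**2
        notch &= ~osteo

    mask = notch.astype(np.uint8)

    # distractor: near-isointense blob just distal to the notch opening
    bottom = cy + b
    dy_c = min(bottom + 5.0, n - 4.0)
    dcx = ncx + rng.uniform(-2, 2)
    distractor = _superellipse(yy - dy_c, xx - dcx, 6.0, w, 2.0) & ~femur

    image = np.full((n, n), config.background_intensity)
    image[femur] = config.femur_intensity
    image[notch] = config.notch_intensity
    image[osteo & femur] = config.femur_intensity
    image[distractor] = config.notch_intensity + config.distractor_contrast
    if config.boundary_blur_sigma_px > 0:
        image = gaussian_filter(image, config.boundary_blur_sigma_px)
    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, image.shape)
    image = np.clip(image, 0.0, 1.0)

    provenance = {
        "generator": "notch",
        "seed": int(seed),
        "config": asdict(config),
        "template": template,
        "has_osteophyte": has_osteo,
        "femur_diameter_mm": float(d_mm),
        "notch_width_mm": float(w_mm),
        "distractor_region": distractor,
    }
    return ImageSample(image, mask, s, provenance)


def generate_knee_phantom(config: PhantomConfig, seed: int) -> ImageSample:
    """Five-class coronal knee phantom: 0 background, 1 femur, 2 tibia,
    3 meniscus, 4 cruciate ligament."""
    if config.n_classes != 5:
        raise PhantomConfigError(
            f"the knee phantom needs n_classes=5, got {config.n_classes}"
        )
    rng = np.random.default_rng(seed)
    n = config.image_size_px
    s = config.pixel_spacing_mm
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)

    d_mm = min(config.femur_diameter_mm, n * s)
    a = d_mm / s / 2.0
    cxf = (n - 1) / 2.0 + rng.uniform(-1.5, 1.5)
    cxf = float(np.clip(cxf, a, n - 1 - a))
    femur = _superellipse(yy - 0.25 * n, xx - cxf, 0.22 * n, a, 2.0)
    # shallow intercondylar groove at the distal femur
    groove_w = rng.uniform(4.0, 7.0) / s
    groove = (np.abs(xx - cxf) <= groove_w / 2.0) & (yy >= 0.36 * n)
    femur &= ~groove

    tibia = _superellipse(yy - 0.76 * n, xx - (n - 1) / 2.0,
                          0.22 * n, 0.44 * n, 2.5)

    gap_y = 0.50 * n + rng.uniform(-1, 1)
    meniscus = np.zeros_like(femur)
    for mx in (0.30 * n, 0.70 * n):
        meniscus |= _superellipse(yy - gap_y, xx - (mx + rng.uniform(-1, 1)),
                                  2.5, 6.0, 2.0)
    meniscus &= ~(femur | tibia)

    # oblique cruciate-ligament band across the joint gap
    t = np.linspace(0, 1, 200)
    ly = 0.40 * n + t * 0.22 * n
    lx = cxf + (t - 0.5) * rng.uniform(6, 10)
    lig = np.zeros_like(femur)
    for j, i in zip(ly, lx):
        lig |= (yy - j) ** 2 + (xx - i) ** 2 <= (1.3 / s) ** 2
    lig &= ~(femur | tibia | meniscus)

    mask = np.zeros((n, n), dtype=np.uint8)
    mask[lig] = 4
    mask[meniscus] = 3
    mask[tibia] = 2
    mask[femur] = 1

    image = np.full((n, n), config.background_intensity)
    image[lig] = 0.40
    image[meniscus] = 0.45
    image[tibia] = 0.80
    image[femur] = config.femur_intensity
    if config.boundary_blur_sigma_px > 0:
        image = gaussian_filter(image, config.boundary_blur_sigma_px)
    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, image.shape)
    image = np.clip(image, 0.0, 1.0)

    provenance = {
        "generator": "knee",
        "seed": int(seed),
        "config": asdict(config),
        "femur_diameter_mm": float(d_mm),
    }
    return ImageSample(image, mask, s, provenance)


def generate_phantom(config: PhantomConfig, seed: int) -> ImageSample:
    """Dispatch on `config.n_classes` (2 -> notch task, 5 -> knee task)."""
    if config.n_classes == 2:
        return generate_notch_phantom(config, seed)
    return generate_knee_phantom(config, seed)


def _horizontal_extent_mm(region: np.ndarray, spacing_mm: float) -> float:
    """Widest row span of a binary region, pixel-count inclusive, in mm."""
    rows = np.nonzero(region.any(axis=1))[0]
    best = 0
    for r in rows:
        cols = np.nonzero(region[r])[0]
        best = max(best, cols[-1] - cols[0] + 1)
    return best * spacing_mm


def measure_phantom(sample: ImageSample) -> PhantomGeometryReport:
    """Geometry report: notch width at its widest row, notch pixel-area
    fraction, femur diameter (all in physical units).

    For the binary task the femur region is recovered from the image by
    intensity thresholding (bone is the only tissue above ~0.6); for the
    five-class task it is label 1.
    """
    mask = np.asarray(sample.mask)
    if mask.max() > 1:
        raise ValueError(
            "measure_phantom expects a binary notch mask; the five-class "
            "knee mask has no notch label"
        )
    notch = mask == 1
    femur = np.asarray(sample.image) >= 0.6
    if not notch.any():
        raise ValueError("mask contains no notch-labelled pixels to measure")
    return PhantomGeometryReport(
        notch_width_mm=_horizontal_extent_mm(notch, sample.pixel_spacing_mm),
        notch_area_fraction=float(notch.sum()) / notch.size,
        femur_diameter_mm=_horizontal_extent_mm(femur, sample.pixel_spacing_mm),
        has_osteophyte=bool(sample.provenance.get("has_osteophyte", False)),
    )


def generate_dataset(config: PhantomConfig, n: int, seed: int, out_dir,
                     fmt: str = "png"):
    """Write `n` phantoms plus a CSV manifest; fully reproducible.

    Per-sample seeds are `seed + i`; the manifest lists the file stem,
    per-sample seed and (for the binary task) the geometry report.
    Returns the manifest as a pandas DataFrame.
    """
    import pandas as pd

    from . import io as _io

    if n < 1:
        raise ValueError("need n >= 1 samples")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n):
        sample_seed = int(seed) + i
        sample = generate_phantom(config, sample_seed)
        stem = f"phantom_{i:04d}"
        _io.save_sample(sample, out_dir, stem, fmt=fmt)
        row = {"stem": stem, "seed": sample_seed}
        if config.n_classes == 2:
            rep = measure_phantom(sample)
            row.update(
                notch_width_mm=rep.notch_width_mm,
                notch_area_fraction=rep.notch_area_fraction,
                femur_diameter_mm=rep.femur_diameter_mm,
                has_osteophyte=rep.has_osteophyte,
            )
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
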
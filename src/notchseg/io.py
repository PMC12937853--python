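"""Reading and writing image/mask pairs.

Two on-disk dialects are supported:

* PNG pairs: `<stem>_img.png` (16-bit grayscale, intensities scaled from
  [0, 1]) and `<stem>_msk.png` (8-bit label values 0..4);
* single-slice NIfTI: `<stem>_img.nii.gz` / `<stem>_msk.nii.gz` with the
  pixel spacing carried in the affine.

Plus a simple color overlay writer (ground truth green, prediction red)
for qualitative inspection.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .phantom import ImageSample


def save_sample(sample: ImageSample, out_dir, stem: str, fmt: str = "png"):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt == "png":
        img16 = np.round(np.clip(sample.image, 0, 1) * 65535).astype(np.uint16)
        Image.fromarray(img16).save(out_dir / f"{stem}_img.png")
        Image.fromarray(sample.mask.astype(np.uint8), mode="L").save(
            out_dir / f"{stem}_msk.png"
        )
    elif fmt == "nifti":
        import nibabel as nib

        s = sample.pixel_spacing_mm
        affine = np.diag([s, s, 1.0, 1.0])
        nib.save(
            nib.Nifti1Image(sample.image.astype(np.float32)[..., None], affine),
            out_dir / f"{stem}_img.nii.gz",
        )
        nib.save(
            nib.Nifti1Image(sample.mask.astype(np.uint8)[..., None], affine),
            out_dir / f"{stem}_msk.nii.gz",
        )
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'png' or 'nifti'")


def load_sample(data_dir, stem: str, pixel_spacing_mm: float | None = None
                ) -> ImageSample:
    data_dir = Path(data_dir)
    png = data_dir / f"{stem}_img.png"
    if png.exists():
        img = np.asarray(Image.open(png), dtype=np.float64) / 65535.0
        mask = np.asarray(
            Image.open(data_dir / f"{stem}_msk.png"), dtype=np.int64
        )
        return ImageSample(img, mask, pixel_spacing_mm or 0.5, {"stem": stem})
    nii = data_dir / f"{stem}_img.nii.gz"
    if nii.exists():
        import nibabel as nib

        img_obj = nib.load(nii)
        img = np.asarray(img_obj.dataobj, dtype=np.float64)[..., 0]
        mask = np.asarray(
            nib.load(data_dir / f"{stem}_msk.nii.gz").dataobj, dtype=np.int64
        )[..., 0]
        spacing = pixel_spacing_mm or float(img_obj.affine[0, 0])
        return ImageSample(img, mask, spacing, {"stem": stem})
    raise FileNotFoundError(f"no sample named {stem!r} under {data_dir}")


def list_stems(data_dir) -> list:
    """Sample stems present in a directory (PNG or NIfTI dialect)."""
    data_dir = Path(data_dir)
    stems = sorted(
        p.name[: -len("_img.png")] for p in data_dir.glob("*_img.png")
    )
    stems += sorted(
        p.name[: -len("_img.nii.gz")] for p in data_dir.glob("*_img.nii.gz")
    )
    return stems


def load_mask(data_dir, stem: str) -> np.ndarray:
    """Load just the label mask of a sample (PNG or NIfTI dialect)."""
    data_dir = Path(data_dir)
    png = data_dir / f"{stem}_msk.png"
    if png.exists():
        return np.asarray(Image.open(png), dtype=np.int64)
    nii = data_dir / f"{stem}_msk.nii.gz"
    if nii.exists():
        import nibabel as nib

        return np.asarray(nib.load(nii).dataobj, dtype=np.int64)[..., 0]
    raise FileNotFoundError(f"no mask named {stem!r} under {data_dir}")


def save_mask(mask: np.ndarray, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".png":
        Image.fromarray(mask.astype(np.uint8), mode="L").save(path)
    else:
        import nibabel as nib

        nib.save(
            nib.Nifti1Image(mask.astype(np.uint8)[..., None], np.eye(4)), path
        )


def save_overlay(image: np.ndarray, pred_mask: np.ndarray, path,
                 gt_mask: np.ndarray | None = None):
    """RGB overlay: prediction in red, ground truth (if given) in green."""
    base = np.clip(image, 0, 1)
    rgb = np.stack([base, base, base], axis=-1)
    rgb[pred_mask > 0] = 0.55 * rgb[pred_mask > 0] + 0.45 * np.array([1.0, 0, 0])
    if gt_mask is not None:
        sel = gt_mask > 0
        rgb[sel] = 0.55 * rgb[sel] + 0.45 * np.array([0, 1.0, 0])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.round(rgb * 255).astype(np.uint8)).save(path)
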
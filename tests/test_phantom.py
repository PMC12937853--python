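"""Synthetic knee-slice phantom generator: determinism, geometry bands,
contrast contracts, dataset round trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from notchseg.io import load_sample
from notchseg.phantom import (
    ImageSample,
    PhantomConfig,
    PhantomConfigError,
    generate_dataset,
    generate_knee_phantom,
    generate_notch_phantom,
    measure_phantom,
)


class TestConfigValidation:
    def test_default_config_is_valid(self):
        PhantomConfig()

    @pytest.mark.parametrize(
        "kwargs,match",
        [
            (dict(notch_width_mm_range=(8.0, 5.0)), "lower"),
            (dict(notch_width_mm_range=(0.0, 5.0)), "lower"),
            (dict(femur_diameter_mm=6.0), "notch width"),
            (dict(image_size_px=32, pixel_spacing_mm=0.5), "fit in frame"),
            (dict(distractor_contrast=0.2), "distractor_contrast"),
            (dict(osteophyte_probability=1.5), "osteophyte"),
            (dict(n_classes=3), "n_classes"),
            (dict(noise_sd=-0.1), "nonnegative"),
        ],
    )
    def test_invariant_violations_named(self, kwargs, match):
        with pytest.raises(PhantomConfigError, match=match):
            PhantomConfig(**kwargs)


class TestNotchPhantom:
    def test_seeded_determinism(self):
        cfg = PhantomConfig()
        s1 = generate_notch_phantom(cfg, 7)
        s2 = generate_notch_phantom(cfg, 7)
        assert np.array_equal(s1.image, s2.image)
        assert np.array_equal(s1.mask, s2.mask)
        s3 = generate_notch_phantom(cfg, 8)
        assert not np.array_equal(s1.mask, s3.mask)

    def test_degenerate_no_noise_case(self):
        cfg = PhantomConfig(noise_sd=0.0, boundary_blur_sigma_px=0.0)
        s = generate_notch_phantom(cfg, 1)
        np.testing.assert_allclose(
            s.image[s.mask == 1], cfg.notch_intensity
        )

    def test_mask_marks_a_concave_notch_inside_the_femur(self):
        s = generate_notch_phantom(PhantomConfig(), 3)
        assert set(np.unique(s.mask)) == {0, 1}
        # notch sits strictly inside the bright femur's bounding box
        femur = s.image >= 0.6
        rows_f = np.nonzero(femur.any(axis=1))[0]
        rows_n = np.nonzero(s.mask.any(axis=1))[0]
        assert rows_f[0] < rows_n[0]

    def test_rejects_multiclass_config(self):
        with pytest.raises(PhantomConfigError, match="binary"):
            generate_notch_phantom(PhantomConfig(n_classes=5), 0)

    def test_geometry_bands_over_200_seeds(self):
        cfg = PhantomConfig()
        reps = [
            measure_phantom(generate_notch_phantom(cfg, s))
            for s in range(1, 201)
        ]
        widths = np.array([r.notch_width_mm for r in reps])
        areas = np.array([r.notch_area_fraction for r in reps])
        diam = np.array([r.femur_diameter_mm for r in reps])
        lo, hi = cfg.notch_width_mm_range
        tol = cfg.pixel_spacing_mm
        assert ((widths >= lo - tol) & (widths <= hi + tol)).all()
        assert lo <= widths.mean() <= hi
        assert 0.05 <= areas.mean() <= 0.08
        assert diam.mean() == pytest.approx(cfg.femur_diameter_mm, rel=0.1)
        osteo_rate = np.mean([r.has_osteophyte for r in reps])
        assert 0.2 <= osteo_rate <= 0.4

    def test_distractor_contrast_contract(self):
        cfg = PhantomConfig()
        gaps = []
        for seed in range(1, 31):
            s = generate_notch_phantom(cfg, seed)
            dist = s.provenance["distractor_region"]
            notch = s.mask == 1
            # compare interiors away from the blurred boundary
            gap = abs(
                s.image[dist].mean() - s.image[notch].mean()
            )
            gaps.append(gap)
        allowance = 3 * cfg.noise_sd / np.sqrt(min(dist.sum(), notch.sum()))
        # boundary blur biases region means slightly; allow one extra sd
        assert np.mean(gaps) <= cfg.distractor_contrast + allowance + 0.05

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_labels_always_valid(self, seed):
        s = generate_notch_phantom(PhantomConfig(), seed)
        assert s.mask.min() >= 0 and s.mask.max() < 2
        assert s.image.min() >= 0.0 and s.image.max() <= 1.0


class TestKneePhantom:
    def test_all_five_labels_present(self):
        s = generate_knee_phantom(PhantomConfig(n_classes=5), 3)
        assert set(np.unique(s.mask)) == {0, 1, 2, 3, 4}

    def test_seeded_determinism(self):
        cfg = PhantomConfig(n_classes=5)
        a = generate_knee_phantom(cfg, 11)
        b = generate_knee_phantom(cfg, 11)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.mask, b.mask)

    def test_femur_always_larger_than_meniscus(self):
        cfg = PhantomConfig(n_classes=5)
        for seed in range(1, 51):
            m = generate_knee_phantom(cfg, seed).mask
            assert (m == 1).sum() > (m == 3).sum()

    def test_binary_config_rejected(self):
        with pytest.raises(PhantomConfigError, match="n_classes"):
            generate_knee_phantom(PhantomConfig(), 0)


class TestMeasurePhantom:
    def test_rectangle_width(self):
        mask = np.zeros((16, 16), dtype=np.uint8)
        mask[4:8, 3:13] = 1  # 10 px wide
        img = np.zeros((16, 16))
        img[0:2] = 0.9  # token femur so the femur measurement is defined
        rep = measure_phantom(ImageSample(img, mask, 0.5))
        assert rep.notch_width_mm == pytest.approx(5.0)

    def test_area_fraction_by_direct_count(self):
        mask = np.zeros((16, 16), dtype=np.uint8)
        mask.ravel()[:13] = 1
        img = np.full((16, 16), 0.9)
        rep = measure_phantom(ImageSample(img, mask, 1.0))
        assert rep.notch_area_fraction == pytest.approx(13 / 256)

    def test_empty_notch_rejected(self):
        with pytest.raises(ValueError, match="notch"):
            measure_phantom(
                ImageSample(np.zeros((8, 8)), np.zeros((8, 8), dtype=np.uint8), 1.0)
            )


class TestDataset:
    def test_manifest_entries_and_distinct_seeds(self, tmp_path):
        cfg = PhantomConfig()
        m = generate_dataset(cfg, 4, seed=0, out_dir=tmp_path)
        assert len(m) == 4
        assert m["seed"].nunique() == 4
        assert (tmp_path / "manifest.csv").exists()

    def test_rerun_reproduces_identical_files(self, tmp_path):
        cfg = PhantomConfig()
        generate_dataset(cfg, 3, seed=5, out_dir=tmp_path / "a")
        generate_dataset(cfg, 3, seed=5, out_dir=tmp_path / "b")
        for f in sorted((tmp_path / "a").glob("*.png")):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_manifest_matches_remeasurement_of_written_files(self, tmp_path):
        cfg = PhantomConfig()
        m = generate_dataset(cfg, 5, seed=2, out_dir=tmp_path)
        for _, row in m.iterrows():
            s = load_sample(tmp_path, row["stem"], cfg.pixel_spacing_mm)
            rep = measure_phantom(s)
            assert rep.notch_width_mm == pytest.approx(row["notch_width_mm"])
            assert rep.notch_area_fraction == pytest.approx(
                row["notch_area_fraction"]
            )
            assert rep.femur_diameter_mm == pytest.approx(
                row["femur_diameter_mm"], abs=cfg.pixel_spacing_mm
            )

    def test_nifti_roundtrip(self, tmp_path):
        cfg = PhantomConfig()
        generate_dataset(cfg, 1, seed=9, out_dir=tmp_path, fmt="nifti")
        s = load_sample(tmp_path, "phantom_0000")
        orig = generate_notch_phantom(cfg, 9)
        np.testing.assert_allclose(s.image, orig.image, atol=1e-6)
        np.testing.assert_array_equal(s.mask, orig.mask)
        assert s.pixel_spacing_mm == pytest.approx(cfg.pixel_spacing_mm)

    def test_invalid_n_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_dataset(PhantomConfig(), 0, 0, tmp_path)
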
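"""Standardization and augmentation: luma, resize, crops, orientations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from printqc.preprocess import (
    DEFAULT_CROP_FRACTIONS,
    ORIENTATIONS,
    FeatureMatrix,
    PreprocessConfig,
    augment_test_set,
    build_features,
    crop_center,
    flatten,
    orient,
    orient_array,
    preprocess_dataset,
    resize,
    to_grayscale,
    unflatten,
)
from printqc.render import Dataset, LabeledImage


def make_image(pixels, label="good", defect="none"):
    return LabeledImage(
        pixels=np.asarray(pixels, dtype=np.uint8),
        label=label,
        defect=defect,
        source="user",
        spec_digest="t",
    )


small_rasters = arrays(
    np.uint8, (6, 5), elements=st.integers(min_value=0, max_value=255)
)


class TestGrayscale:
    @pytest.mark.parametrize(
        "rgb, expected",
        [
            ((255, 255, 255), 255),
            ((255, 0, 0), 76),  # round(0.299 * 255), half-up
            ((0, 0, 0), 0),
            ((0, 255, 0), 150),
            ((0, 0, 255), 29),
        ],
    )
    def test_luma_weights(self, rgb, expected):
        image = make_image(np.full((2, 2, 3), rgb, dtype=np.uint8))
        assert to_grayscale(image).pixels[0, 0] == expected

    def test_idempotent(self):
        image = make_image(np.arange(12, dtype=np.uint8).reshape(2, 2, 3))
        once = to_grayscale(image)
        twice = to_grayscale(once)
        assert np.array_equal(once.pixels, twice.pixels)
        assert once.pixels.ndim == 2

    def test_labels_preserved(self):
        image = make_image(np.zeros((2, 2, 3)), label="bad", defect="cracked")
        out = to_grayscale(image)
        assert (out.label, out.defect) == ("bad", "cracked")


class TestResize:
    def test_identity_resize_is_pixel_identical(self):
        image = make_image(np.random.default_rng(0).integers(0, 256, (32, 32, 3)))
        assert np.array_equal(resize(image, 32).pixels, image.pixels)

    def test_constant_image_stays_constant(self):
        image = make_image(np.full((48, 80), 137, dtype=np.uint8))
        out = resize(image, 16)
        assert np.all(out.pixels == 137)
        assert out.pixels.shape == (16, 16)

    def test_aspect_ratio_not_preserved(self):
        image = make_image(np.zeros((10, 100), dtype=np.uint8))
        assert resize(image, 25).pixels.shape == (25, 25)

    def test_grayscale_resize_commutation_tolerance(self, small_good_spec):
        """resize-then-gray and gray-then-resize agree within 2 intensity
        units per pixel on a smooth render."""
        from printqc.render import render_form

        image = render_form(small_good_spec)
        a = to_grayscale(resize(image, 64)).pixels.astype(int)
        b = resize(to_grayscale(image), 64).pixels.astype(int)
        assert np.abs(a - b).max() <= 2


class TestCropCenter:
    def test_full_fraction_is_identity(self):
        image = make_image(np.random.default_rng(1).integers(0, 256, (9, 9)))
        assert np.array_equal(crop_center(image, 1.0).pixels, image.pixels)

    def test_half_crop_window_arithmetic(self):
        px = np.zeros((100, 100), dtype=np.uint8)
        px[25:75, 25:75] = 200
        out = crop_center(make_image(px), 0.5)
        assert out.pixels.shape == (50, 50)
        assert np.all(out.pixels == 200)

    @pytest.mark.parametrize("bad", [0.0, -0.2, 1.5])
    def test_fraction_out_of_range(self, bad):
        with pytest.raises(ValueError):
            crop_center(make_image(np.zeros((4, 4))), bad)

    def test_foreground_share_grows_as_fraction_shrinks(self, small_good_spec):
        from printqc.render import render_form

        image = to_grayscale(render_form(small_good_spec))
        shares = []
        for f in (1.0, 0.8, 0.6):
            cropped = crop_center(image, f)
            shares.append(np.mean(cropped.pixels > 100))
        assert shares == sorted(shares)


class TestOrient:
    @settings(max_examples=25, deadline=None)
    @given(small_rasters)
    def test_group_identities(self, px):
        assert np.array_equal(
            orient_array(px, "rot180"), orient_array(orient_array(px, "vflip"), "hflip")
        )
        assert np.array_equal(orient_array(orient_array(px, "hflip"), "hflip"), px)
        assert np.array_equal(orient_array(orient_array(px, "vflip"), "vflip"), px)

    def test_vflip_definition_on_2x2(self):
        px = np.array([[1, 2], [3, 4]], dtype=np.uint8)
        assert np.array_equal(orient_array(px, "vflip"), np.array([[3, 4], [1, 2]]))

    def test_label_preserved(self):
        image = make_image(np.zeros((3, 3)), label="bad", defect="cracked")
        out = orient(image, "rot180")
        assert (out.label, out.defect) == ("bad", "cracked")


class TestAugmentTestSet:
    def _gray_dataset(self, n, size=16):
        rng = np.random.default_rng(3)
        items = [
            make_image(rng.integers(0, 256, (size, size)), label=("good" if i % 2 else "bad"))
            for i in range(n)
        ]
        return Dataset(items=items, metadata={"form": "tablet"})

    def test_16x_expansion(self):
        ds = self._gray_dataset(4)
        out = augment_test_set(ds, DEFAULT_CROP_FRACTIONS)
        assert len(out) == 64

    def test_provenance_tuples_distinct(self):
        ds = self._gray_dataset(1)
        out = augment_test_set(ds)
        assert len(out) == 16
        assert len({im.spec_digest for im in out}) == 16
        assert all(im.source == "augmented" for im in out)

    def test_class_balance_preserved(self):
        ds = self._gray_dataset(10)
        out = augment_test_set(ds)
        assert out.class_counts() == {"good": 80, "bad": 80}

    def test_duplicate_fractions_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            augment_test_set(self._gray_dataset(1), (0.9, 0.9, 0.7, 0.6))

    def test_color_input_rejected(self):
        ds = Dataset(items=[make_image(np.zeros((8, 8, 3)))], metadata={})
        with pytest.raises(ValueError, match="grayscale"):
            augment_test_set(ds)


class TestFlatten:
    def test_feature_dimensions(self):
        rng = np.random.default_rng(0)
        gray_cfg = PreprocessConfig(target_size_px=50, color_space="gray")
        rgb_cfg = PreprocessConfig(target_size_px=25, color_space="rgb")
        gray = Dataset(
            items=[make_image(rng.integers(0, 256, (50, 50))) for _ in range(3)]
        )
        rgb = Dataset(
            items=[make_image(rng.integers(0, 256, (25, 25, 3))) for _ in range(3)]
        )
        assert flatten(gray, gray_cfg).d == 2500
        assert flatten(rgb, rgb_cfg).d == 1875

    def test_round_trip_reproduces_pixels(self):
        cfg = PreprocessConfig(target_size_px=8, color_space="gray", intensity_scale="unit_0_1")
        px = np.random.default_rng(5).integers(0, 256, (8, 8)).astype(np.uint8)
        fm = flatten(Dataset(items=[make_image(px)]), cfg)
        assert np.array_equal(unflatten(fm.values[0], cfg), px)

    def test_mixed_shapes_error_names_rows(self):
        cfg = PreprocessConfig(target_size_px=8, color_space="gray")
        ds = Dataset(
            items=[make_image(np.zeros((8, 8))), make_image(np.zeros((9, 9)))]
        )
        with pytest.raises(ValueError, match=r"rows \[1\]"):
            flatten(ds, cfg)

    def test_build_features_standardizes_then_flattens(self):
        ds = Dataset(items=[make_image(np.zeros((12, 10, 3)))])
        cfg = PreprocessConfig(target_size_px=8, color_space="gray")
        fm = build_features(ds, cfg)
        assert fm.values.shape == (1, 64)
        assert fm.values.max() <= 1.0


def test_feature_matrix_persistence_round_trip(tmp_path):
    """Compressed store + manifest reload to an identical matrix."""
    from printqc.preprocess import load_features, save_features

    cfg = PreprocessConfig(target_size_px=8, color_space="gray")
    fm = FeatureMatrix(
        np.random.default_rng(0).uniform(size=(3, 64)),
        np.array(["good", "bad", "good"]),
        ["a", "b", "c"],
        cfg,
    )
    save_features(fm, tmp_path / "fm")
    back = load_features(tmp_path / "fm")
    assert np.array_equal(back.values, fm.values)
    assert list(back.labels) == list(fm.labels)
    assert back.row_provenance == fm.row_provenance
    assert back.config == cfg
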
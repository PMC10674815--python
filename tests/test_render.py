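"""Renderer geometry, determinism, corpus composition and OOD properties."""

import math

import numpy as np
import pytest
from scipy import ndimage
from scipy.stats import chisquare

from printqc.preprocess import to_grayscale
from printqc.render import (
    DEFECTS,
    FormGeometry,
    OODSpec,
    RenderSpec,
    generate_ood_set,
    generate_pseudo_real_set,
    generate_training_set,
    render_form,
    render_form_layers,
    silhouette_mask,
)


class TestGeometryFidelity:
    def test_tablet_disc_area_matches_analytic(self):
        """Flood-counted tablet foreground equals pi*r^2 within 2%."""
        geom = FormGeometry(
            form="tablet", length_mm=10, width_mm=10, px_per_mm=20, canvas_px=512
        )
        spec = RenderSpec(geometry=geom, quality="good", defect="none", seed=0)
        _, masks = render_form_layers(spec)
        area = masks["foreground"].sum()
        r_px = 5 * 20  # (10 mm / 2) * 20 px/mm = 100 px
        assert area == pytest.approx(math.pi * r_px**2, rel=0.02)

    @pytest.mark.parametrize("px_per_mm", [5, 11, 20])
    def test_capsule_stadium_area(self, px_per_mm):
        """Capsule silhouette equals the analytic stadium area within 5%."""
        geom = FormGeometry(
            form="capsule", length_mm=18, width_mm=8, px_per_mm=px_per_mm, canvas_px=512
        )
        mask = silhouette_mask(geom)
        r = 4 * px_per_mm
        rect = (18 - 8) * px_per_mm * 8 * px_per_mm
        assert mask.sum() == pytest.approx(rect + math.pi * r**2, rel=0.05)

    def test_film_bounding_box_aspect_ratio(self):
        """A 30 x 10 mm film has a 3:1 foreground bounding box within 5%."""
        geom = FormGeometry.default("film", canvas_px=512)
        spec = RenderSpec(geometry=geom, quality="good", defect="none", seed=3)
        _, masks = render_form_layers(spec)
        rows = np.any(masks["foreground"], axis=1)
        cols = np.any(masks["foreground"], axis=0)
        height = np.ptp(rows.nonzero()[0]) + 1
        width = np.ptp(cols.nonzero()[0]) + 1
        assert width / height == pytest.approx(3.0, rel=0.05)

    def test_silhouette_exceeding_canvas_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            FormGeometry(form="film", length_mm=30, width_mm=10, px_per_mm=20, canvas_px=512)


class TestRenderForm:
    def test_same_spec_is_byte_identical(self, small_good_spec):
        a = render_form(small_good_spec)
        b = render_form(small_good_spec)
        assert np.array_equal(a.pixels, b.pixels)

    def test_label_and_defect_copied_from_spec(self, small_tablet_geom):
        spec = RenderSpec(
            geometry=small_tablet_geom, quality="bad", defect="under_cured", seed=5
        )
        image = render_form(spec)
        assert (image.label, image.defect) == ("bad", "under_cured")

    def test_inconsistent_quality_defect_rejected(self, small_tablet_geom):
        with pytest.raises(ValueError):
            RenderSpec(geometry=small_tablet_geom, quality="good", defect="cracked")
        with pytest.raises(ValueError):
            RenderSpec(geometry=small_tablet_geom, quality="bad", defect="none")

    def test_crack_spans_body_to_the_boundary(self, small_tablet_geom):
        """Each crack is a connected polyline whose endpoints reach within
        3 px of the silhouette boundary."""
        spec = RenderSpec(
            geometry=small_tablet_geom, quality="bad", defect="cracked", seed=11
        )
        _, masks = render_form_layers(spec)
        crack = masks["crack"]
        assert crack.any()
        silhouette = silhouette_mask(small_tablet_geom)
        boundary = silhouette & ~ndimage.binary_erosion(silhouette, iterations=3)
        labeled, n_components = ndimage.label(crack, structure=np.ones((3, 3)))
        for comp in range(1, n_components + 1):
            assert (crack & (labeled == comp) & boundary).any()


class TestTrainingSet:
    def test_default_composition_100_100_with_defect_thirds(self):
        ds = generate_training_set("capsule", 100, 100, seed=1, canvas_px=128)
        assert ds.class_counts() == {"good": 100, "bad": 100}
        assert ds.defect_counts() == {"cracked": 34, "over_cured": 33, "under_cured": 33}

    def test_minimal_bad_split_is_even(self):
        ds = generate_training_set("tablet", 2, 3, seed=7, canvas_px=128)
        assert len(ds) == 5
        assert ds.defect_counts() == {"cracked": 1, "over_cured": 1, "under_cured": 1}

    def test_deterministic_and_seed_sensitive(self):
        a = generate_training_set("film", 4, 3, seed=5, canvas_px=128)
        b = generate_training_set("film", 4, 3, seed=5, canvas_px=128)
        c = generate_training_set("film", 4, 3, seed=6, canvas_px=128)
        for x, y in zip(a, b):
            assert np.array_equal(x.pixels, y.pixels)
        assert any(
            not np.array_equal(x.pixels, y.pixels) for x, y in zip(a, c)
        )

    def test_too_few_bad_rejected(self):
        with pytest.raises(ValueError, match="n_bad"):
            generate_training_set("tablet", 5, 2, seed=0, canvas_px=128)


class TestPseudoRealSet:
    def test_balance_and_defect_thirds(self):
        ds = generate_pseudo_real_set("film", 200, seed=3, canvas_px=256)
        assert ds.class_counts() == {"good": 100, "bad": 100}
        assert ds.defect_counts() == {"cracked": 34, "over_cured": 33, "under_cured": 33}

    def test_minimal_even_set(self):
        ds = generate_pseudo_real_set("tablet", 6, seed=0, canvas_px=256)
        assert ds.class_counts() == {"good": 3, "bad": 3}
        assert sorted(ds.defect_counts()) == sorted(DEFECTS)

    def test_odd_n_rejected(self):
        with pytest.raises(ValueError, match="even"):
            generate_pseudo_real_set("tablet", 7, seed=0, canvas_px=256)

    def test_low_chroma_palette(self):
        """Per-pixel channel spreads stay within 15 + 3*noise_sd (noise is
        shared across channels, so the bound holds with margin)."""
        ds = generate_pseudo_real_set("capsule", 6, seed=4, canvas_px=256)
        bound = 15 + 3 * 4.0
        for image in ds:
            px = image.pixels.astype(int)
            assert np.abs(px[:, :, 0] - px[:, :, 1]).max() <= bound
            assert np.abs(px[:, :, 1] - px[:, :, 2]).max() <= bound

    def test_canvas_at_least_twice_training_default(self):
        ds = generate_pseudo_real_set("tablet", 6, seed=0)
        assert ds[0].shape[0] >= 2 * 512


class TestOODSet:
    def test_noise_histograms_are_uniform(self):
        """Chi-square against a uniform 256-bin histogram, p > 0.001."""
        ds = generate_ood_set(OODSpec(kind="noise", n=3, canvas_px=128, seed=5))
        for image in ds:
            for channel in range(3):
                counts, _ = np.histogram(
                    image.pixels[:, :, channel], bins=256, range=(0, 256)
                )
                assert chisquare(counts).pvalue > 0.001

    def test_background_is_near_constant(self):
        ds = generate_ood_set(OODSpec(kind="background", n=1, canvas_px=64, seed=0))
        assert ds[0].pixels.std() <= 1.0

    def test_shapes_have_one_connected_component(self):
        ds = generate_ood_set(OODSpec(kind="oblong", n=10, canvas_px=256, seed=2))
        for image in ds:
            gray = to_grayscale(image).pixels
            bg = np.bincount(gray.reshape(-1)).argmax()
            fg = np.abs(gray.astype(int) - int(bg)) > 8
            _, n_components = ndimage.label(fg)
            assert n_components == 1

    def test_all_ood_labeled_bad_with_requested_count(self):
        ds = generate_ood_set(OODSpec(kind="triangle", n=7, canvas_px=64, seed=1))
        assert len(ds) == 7
        assert all(im.label == "bad" and im.source == "ood" for im in ds)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            OODSpec(kind="square", n=1, canvas_px=64, seed=0)


def test_virtual_corpus_is_separable_by_a_decision_tree():
    """A depth-unlimited tree trained on 136 virtual images classifies 64
    held-out virtual images at >= 90%: the defect renderings are learnable."""
    from printqc.models import ModelSpec, train
    from printqc.preprocess import FeatureMatrix, PreprocessConfig, build_features

    cfg = PreprocessConfig(target_size_px=125, color_space="gray")
    ds = generate_training_set("tablet", 100, 100, seed=1)
    fm = build_features(ds, cfg)
    idx = np.arange(200)
    np.random.default_rng(0).shuffle(idx)
    fit_rows, held_rows = idx[:136], idx[136:]
    fitted = train(
        ModelSpec(technique="DT", seed=0, tuned=False),
        FeatureMatrix(fm.values[fit_rows], fm.labels[fit_rows], [""] * 136, cfg),
    )
    held = FeatureMatrix(fm.values[held_rows], fm.labels[held_rows], [""] * 64, cfg)
    accuracy = np.mean(fitted.predict_label(held) == held.labels)
    assert accuracy >= 0.90
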
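"""Classical post-processing operators."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from somaquant.imaging import LabelMask, MultiChannelImage
from somaquant.postprocess import (estimate_background, fill_holes,
                                   morph_refine, watershed_split, zero_channel)


def disc_mask(shape, center, radius):
    yy, xx = np.ogrid[:shape[0], :shape[1]]
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius ** 2


def border_flood_fill_oracle(mask):
    """Fill holes by flooding the background from the border (4-conn)."""
    bg = ~mask
    labels, _ = ndi.label(bg, structure=ndi.generate_binary_structure(2, 1))
    border_labels = set(labels[0, :]) | set(labels[-1, :]) \
        | set(labels[:, 0]) | set(labels[:, -1])
    border_labels.discard(0)
    outside = np.isin(labels, list(border_labels))
    return mask | (bg & ~outside)


class TestWatershedSplit:
    def test_single_disc_stays_one_region(self):
        mask = disc_mask((40, 40), (20, 20), 10)
        out = watershed_split(mask, min_peak_distance=5)
        assert out.labels.max() == 1
        np.testing.assert_array_equal(out.labels > 0, mask)

    def test_two_overlapping_discs_split_into_two(self):
        mask = disc_mask((50, 60), (20, 25), 10) | \
            disc_mask((50, 60), (34, 25), 10)  # centres 14 px apart
        out = watershed_split(mask, min_peak_distance=8)
        assert out.labels.max() == 2
        np.testing.assert_array_equal(out.labels > 0, mask)
        # nearest-peak assignment: each disc centre keeps its own label
        assert out.labels[25, 20] != out.labels[25, 34]

    def test_empty_mask_gives_zero_regions(self):
        out = watershed_split(np.zeros((10, 10), dtype=bool), 3)
        assert out.labels.max() == 0

    def test_regions_partition_foreground(self, rng):
        for _ in range(20):
            mask = ndi.binary_dilation(rng.random((48, 48)) > 0.93,
                                       iterations=2)
            out = watershed_split(mask, min_peak_distance=4)
            np.testing.assert_array_equal(out.labels > 0, mask)

    def test_region_count_monotone_in_peak_distance(self):
        mask = disc_mask((60, 90), (20, 30), 9) | \
            disc_mask((60, 90), (34, 30), 9) | disc_mask((60, 90), (60, 30), 9)
        counts = [watershed_split(mask, d).labels.max() for d in (3, 8, 30)]
        assert counts == sorted(counts, reverse=True)

    def test_deterministic(self, rng):
        mask = rng.random((40, 40)) > 0.8
        a = watershed_split(mask, 3).labels
        b = watershed_split(mask, 3).labels
        np.testing.assert_array_equal(a, b)


class TestMorphRefine:
    def test_erode_dilate_removes_one_pixel_bridge(self):
        mask = np.zeros((30, 60), dtype=bool)
        mask |= disc_mask((30, 60), (15, 15), 8)
        mask |= disc_mask((30, 60), (45, 15), 8)
        mask[15, 15:46] = True  # 1-px bridge
        out = morph_refine(mask, radius=2, sequence=["erode", "dilate"])
        n_components, _ = ndi.label(out)[1], None
        assert ndi.label(out)[1] == 2

    def test_opening_of_large_convex_blob_is_identity(self):
        mask = disc_mask((50, 50), (25, 25), 15)
        out = morph_refine(mask, radius=2, sequence=["erode", "dilate"])
        np.testing.assert_array_equal(out, mask)

    def test_morphology_ordering(self, rng):
        for _ in range(25):
            mask = rng.random((32, 32)) > 0.7
            eroded = morph_refine(mask, 1, ["erode"])
            dilated = morph_refine(mask, 1, ["dilate"])
            assert np.all(eroded <= mask)
            assert np.all(mask <= dilated)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            morph_refine(np.zeros((5, 5), bool), radius=0, sequence=["erode"])
        with pytest.raises(ValueError):
            morph_refine(np.zeros((5, 5), bool), radius=1, sequence=["open"])


class TestFillHoles:
    def test_annulus_becomes_solid_disc(self):
        outer = disc_mask((40, 40), (20, 20), 12)
        inner = disc_mask((40, 40), (20, 20), 6)
        filled = fill_holes(outer & ~inner)
        np.testing.assert_array_equal(filled, outer)

    def test_solid_blob_unchanged_idempotent(self):
        mask = disc_mask((30, 30), (15, 15), 9)
        once = fill_holes(mask)
        np.testing.assert_array_equal(once, mask)
        np.testing.assert_array_equal(fill_holes(once), once)

    def test_matches_border_flood_oracle_on_random_masks(self, rng):
        for _ in range(100):
            mask = rng.random((24, 24)) > 0.55
            np.testing.assert_array_equal(fill_holes(mask),
                                          border_flood_fill_oracle(mask))

    def test_never_removes_foreground(self, rng):
        for _ in range(20):
            mask = rng.random((20, 20)) > 0.5
            assert np.all(mask <= fill_holes(mask))

    def test_instance_holes_keep_instance_label(self):
        outer = disc_mask((40, 40), (20, 20), 10)
        inner = disc_mask((40, 40), (20, 20), 4)
        labels = np.where(outer & ~inner, 3, 0).astype(np.int32)
        out = fill_holes(LabelMask(labels, kind="instance"))
        assert np.all(out.labels[inner] == 3)


class TestZeroChannel:
    def make_image(self, rng):
        return MultiChannelImage(rng.random((10, 10, 3)),
                                 ["marker", "target", "nuclear"])

    def test_idempotent(self, rng):
        img = self.make_image(rng)
        once = zero_channel(img, "target")
        twice = zero_channel(once, "target")
        np.testing.assert_array_equal(once.pixels, twice.pixels)

    def test_other_channels_untouched_and_target_zero(self, rng):
        img = self.make_image(rng)
        out = zero_channel(img, "target")
        assert np.all(out.channel("target") == 0.0)
        np.testing.assert_array_equal(out.channel("marker"),
                                      img.channel("marker"))
        np.testing.assert_array_equal(out.channel("nuclear"),
                                      img.channel("nuclear"))

    def test_unknown_channel_raises(self, rng):
        with pytest.raises(KeyError):
            zero_channel(self.make_image(rng), "brightfield")


class TestEstimateBackground:
    def test_uniform_image_mean_exact_sd_zero(self):
        img = MultiChannelImage(np.full((20, 20, 2), 0.06), ["a", "b"])
        bg = estimate_background(img)
        np.testing.assert_allclose(bg.mean, 0.06)
        np.testing.assert_allclose(bg.sd, 0.0, atol=1e-12)
        assert bg.n_pixels == 400

    def test_bright_image_has_no_background_pixels(self):
        img = MultiChannelImage(np.full((10, 10, 1), 0.5), ["a"])
        with pytest.raises(ValueError, match="threshold"):
            estimate_background(img, threshold=40 / 255)

    def test_threshold_outside_allowed_range_rejected(self):
        img = MultiChannelImage(np.full((5, 5, 1), 0.01), ["a"])
        with pytest.raises(ValueError, match="range"):
            estimate_background(img, threshold=0.5)

    def test_recovers_gaussian_background_mean(self, rng):
        true_mean, true_sd = 0.05, 0.01
        pixels = np.clip(rng.normal(true_mean, true_sd, (64, 64, 1)), 0, 1)
        img = MultiChannelImage(pixels, ["a"])
        bg = estimate_background(img)
        se = true_sd / np.sqrt(bg.n_pixels)
        assert abs(bg.mean[0] - true_mean) < 2 * se + 1e-4

    def test_exclusion_mask_respected(self):
        pixels = np.full((10, 10, 1), 0.05)
        pixels[:5] = 0.06
        img = MultiChannelImage(pixels, ["a"])
        exclude = np.zeros((10, 10), bool)
        exclude[:5] = True
        bg = estimate_background(img, exclude_mask=exclude)
        assert bg.n_pixels == 50
        np.testing.assert_allclose(bg.mean, 0.05)
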
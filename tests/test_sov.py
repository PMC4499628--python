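"""Sinus-of-Valsalva detection: cropping, thresholding, object filtering."""

import numpy as np
import pytest

from avaplan.errors import ConfigurationError, DetectionError, InputError
from avaplan.io import BinaryMask, GrayImage
from avaplan.phantom import PhantomSpec, generate_phantom
from avaplan.sov import (
    SovConfig,
    clear_border_objects,
    crop_image,
    detect_sov,
    global_threshold,
    preliminary_crop,
    remove_small_objects,
)

from conftest import random_mask
from oracles import clear_border_oracle, otsu_between_class_variance, remove_small_oracle

SP = (0.5, 0.5)


def _mask(data):
    return BinaryMask(np.asarray(data, dtype=bool), SP)


class TestPreliminaryCrop:
    def test_full_fraction_is_identity(self, default_phantom):
        img, _ = default_phantom
        window, region = preliminary_crop(img, 1.0)
        assert window.shape == img.shape
        assert (region.row_start, region.col_start) == (0, 0)

    def test_half_fraction_gives_centered_half_window(self):
        img = GrayImage(np.zeros((512, 512)), SP)
        window, region = preliminary_crop(img, 0.5)
        assert window.shape == (256, 256)
        assert (region.row_start, region.row_stop) == (128, 384)
        assert (region.col_start, region.col_stop) == (128, 384)

    def test_default_window_contains_whole_phantom_root(self, default_phantom):
        img, truth = default_phantom
        _, region = preliminary_crop(img, 0.5)
        rows, cols = np.nonzero(truth.sov_mask.data)
        assert region.row_start <= rows.min() and rows.max() < region.row_stop
        assert region.col_start <= cols.min() and cols.max() < region.col_stop

    def test_tiny_window_rejected(self):
        img = GrayImage(np.zeros((64, 64)), SP)
        with pytest.raises(ConfigurationError, match="32"):
            preliminary_crop(img, 0.25)

    @pytest.mark.parametrize("fraction", [0.0, 1.5])
    def test_invalid_fraction_rejected(self, fraction):
        img = GrayImage(np.zeros((64, 64)), SP)
        with pytest.raises(ConfigurationError):
            preliminary_crop(img, fraction)


class TestGlobalThreshold:
    def test_two_valued_image_separated(self):
        data = np.full((32, 32), 10.0)
        data[8:24, 8:24] = 200.0
        level = global_threshold(GrayImage(data, SP))
        assert 10.0 < level < 200.0

    def test_constant_image_rejected(self):
        with pytest.raises(InputError, match="constant"):
            global_threshold(GrayImage(np.full((16, 16), 5.0), SP))

    def test_noiseless_phantom_foreground_covers_lumen_not_background(self, default_phantom):
        img, truth = default_phantom
        level = global_threshold(img)
        fg = img.data > level
        spec = PhantomSpec()
        lumen = (img.data == spec.intensity_lumen) & truth.sov_mask.data
        background = ~truth.sov_mask.data
        assert (fg & lumen).sum() == lumen.sum()
        assert not (fg & background).any()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_achieves_exhaustive_between_class_variance_maximum(self, seed):
        # a wide empty valley makes the variance profile flat, so compare the
        # achieved objective rather than the argmax position
        rng = np.random.default_rng(seed)
        data = np.concatenate(
            [rng.normal(60, 8, 4000), rng.normal(190, 12, 2500)]
        ).reshape(-1, 50)
        data = np.clip(data, 0, 255)
        level = global_threshold(GrayImage(data, SP))
        centers, variances = otsu_between_class_variance(data)
        achieved = variances[np.nanargmin(np.abs(centers - level))]
        assert achieved >= 0.999 * np.nanmax(variances)


class TestRemoveSmallObjects:
    def test_699_removed_700_kept(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[:35, :20] = True  # 700 px block
        out = remove_small_objects(_mask(mask), 700)
        assert out.count == 700
        mask699 = mask.copy()
        mask699[34, 19] = False  # 699 px
        assert remove_small_objects(_mask(mask699), 700).count == 0

    @pytest.mark.parametrize("seed", list(range(5)))
    def test_agrees_with_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = random_mask(rng, (32, 32), 0.4)
        out = remove_small_objects(_mask(mask), 5)
        assert np.array_equal(out.data, remove_small_oracle(mask, 5))

    def test_monotone_and_idempotent(self, rng):
        mask = random_mask(rng, (32, 32), 0.4)
        once = remove_small_objects(_mask(mask), 6)
        assert not (once.data & ~mask).any()
        twice = remove_small_objects(once, 6)
        assert np.array_equal(once.data, twice.data)


class TestClearBorderObjects:
    def test_centered_disc_unchanged_clipped_disc_removed(self):
        rr, cc = np.mgrid[0:33, 0:33]
        centered = (rr - 16) ** 2 + (cc - 16) ** 2 <= 64
        assert clear_border_objects(_mask(centered)).count == centered.sum()
        clipped = (rr - 2) ** 2 + (cc - 16) ** 2 <= 64  # touches the top edge
        assert clear_border_objects(_mask(clipped)).count == 0

    def test_mixed_discs_keep_only_interior(self):
        rr, cc = np.mgrid[0:48, 0:48]
        interior = (rr - 30) ** 2 + (cc - 30) ** 2 <= 36
        clipped = (rr - 3) ** 2 + (cc - 8) ** 2 <= 36
        out = clear_border_objects(_mask(interior | clipped))
        assert np.array_equal(out.data, interior)

    @pytest.mark.parametrize("seed", list(range(5)))
    def test_agrees_with_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        mask = random_mask(rng, (32, 32), 0.35)
        out = clear_border_objects(_mask(mask))
        assert np.array_equal(out.data, clear_border_oracle(mask))


class TestDetectSov:
    def test_region_contains_whole_truth_root(self, default_phantom):
        img, truth = default_phantom
        region = detect_sov(img)
        rows, cols = np.nonzero(truth.sov_mask.data)
        assert region.row_start <= rows.min() and rows.max() < region.row_stop
        assert region.col_start <= cols.min() and cols.max() < region.col_stop

    def test_clean_image_region_equals_padded_bbox(self):
        # bright disc on plain background: detected box = disc bbox + pad
        rr, cc = np.mgrid[0:128, 0:128]
        disc = (rr - 64) ** 2 + (cc - 64) ** 2 <= 24**2
        img = GrayImage(np.where(disc, 200.0, 20.0), SP)
        region = detect_sov(img, SovConfig(central_fraction=1.0, bbox_pad_fraction=0.1))
        rows, cols = np.nonzero(disc)
        pad = int(round((rows.max() - rows.min() + 1) * 0.1))
        assert region.row_start == rows.min() - pad
        assert region.row_stop == rows.max() + 1 + pad
        assert region.col_start == cols.min() - pad

    def test_all_background_image_raises_detection_failure(self):
        rng = np.random.default_rng(2)
        img = GrayImage(rng.uniform(10, 30, (128, 128)), SP)
        with pytest.raises(DetectionError, match="manually"):
            detect_sov(img)

    def test_idempotent_on_already_cropped_root(self, default_phantom):
        img, truth = default_phantom
        region = detect_sov(img)
        cropped = crop_image(img, region)
        again = detect_sov(cropped, SovConfig(central_fraction=1.0))
        rows, cols = np.nonzero(
            truth.sov_mask.data[region.row_start : region.row_stop, region.col_start : region.col_stop]
        )
        assert again.row_start <= rows.min() and rows.max() < again.row_stop
        assert again.col_start <= cols.min() and cols.max() < again.col_stop
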
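"""Adaptive calcium threshold: hand-traced tables, algebraic properties, phantoms."""

import numpy as np
import pytest

from avaplan.calcium import (
    CalciumConfig,
    compute_histogram,
    detect_calcium,
    estimate_calcium_threshold,
    filter_calcium_mask,
    normalize_8bit,
)
from avaplan.errors import InputError
from avaplan.io import BinaryMask, GrayImage
from avaplan import sov as sov_mod

SP = (0.5, 0.5)


def hist_from(pairs):
    h = np.zeros(256, dtype=int)
    for bin_idx, count in pairs:
        h[bin_idx] = count
    return h


class TestNormalize8bit:
    def test_full_range_image_unchanged(self):
        data = np.rint(np.linspace(0, 255, 64)).reshape(8, 8)
        out = normalize_8bit(GrayImage(data, SP))
        assert np.array_equal(out.data, data)

    def test_two_valued_maps_to_extremes(self):
        data = np.where(np.arange(16).reshape(4, 4) % 2 == 0, 37.0, 1200.0)
        out = normalize_8bit(GrayImage(data, SP))
        assert set(np.unique(out.data)) == {0.0, 255.0}

    def test_range_contract_and_constant_error(self, rng):
        out = normalize_8bit(GrayImage(rng.uniform(-500, 3000, (16, 16)), SP))
        assert out.data.min() == 0.0 and out.data.max() == 255.0
        with pytest.raises(InputError, match="constant"):
            normalize_8bit(GrayImage(np.full((4, 4), 9.0), SP))


# Each case traced by hand through the five steps: (histogram, im_max, max_h,
# t_calc_est, dr, branch, t_calc).
HAND_TRACED = [
    # dominant dark peak, dark branch (dr=50 < 0.7*200)
    (hist_from([(50, 1000), (60, 400), (200, 100)]), 200, 1000, 60, 50, "dark", 88.0),
    # bright image: half-mass reached at bin 250 > 0.7*255 -> bright branch
    (hist_from([(240, 500), (250, 900), (255, 50)]), 255, 900, 250, 250, "bright", 252.5),
    # single occupied bin: est = im_max, both branches give t_calc = im_max
    (hist_from([(77, 100)]), 77, 100, 77, 77, "bright", 77.0),
    # dr exactly equals 0.7*im_max: tie assigned to the dark branch
    (hist_from([(140, 800), (180, 500), (200, 200)]), 200, 800, 180, 140, "dark", 184.0),
    # count exactly MaxH/3 stops the downward scan (inclusive "reaching")
    (hist_from([(30, 900), (150, 300), (200, 10)]), 200, 900, 150, 30, "dark", 160.0),
    # cumulative exactly half stops the DR scan (inclusive "reaching")
    (hist_from([(10, 500), (20, 500), (100, 10)]), 100, 500, 20, 20, "dark", 36.0),
]


class TestEstimateThreshold:
    @pytest.mark.parametrize("h,im_max,max_h,est,dr,branch,t_calc", HAND_TRACED)
    def test_hand_traced_histograms_reproduced_exactly(
        self, h, im_max, max_h, est, dr, branch, t_calc
    ):
        s = estimate_calcium_threshold(h)
        assert (s.im_max, s.max_h, s.t_calc_est, s.dr) == (im_max, max_h, est, dr)
        assert s.branch == branch
        assert s.t_calc == t_calc

    def test_empty_histogram_rejected(self):
        with pytest.raises(InputError, match="empty"):
            estimate_calcium_threshold(np.zeros(256, dtype=int))

    @pytest.mark.parametrize("seed", range(10))
    def test_threshold_bracketed_and_branches_ordered(self, seed):
        rng = np.random.default_rng(seed)
        h = rng.integers(0, 500, 256)
        s = estimate_calcium_threshold(h)
        assert 0 <= s.t_calc_est <= s.t_calc <= s.im_max
        bright = CalciumConfig(dr_factor=-1.0)   # force bright branch
        dark = CalciumConfig(dr_factor=300.0)    # force dark branch
        sb = estimate_calcium_threshold(h, bright)
        sd = estimate_calcium_threshold(h, dark)
        assert sb.branch == "bright" and sd.branch == "dark"
        assert sb.t_calc >= sd.t_calc

    def test_shift_covariance_on_random_histograms(self):
        rng = np.random.default_rng(2024)
        tested = 0
        while tested < 100:
            h = np.zeros(256, dtype=int)
            occ = rng.integers(0, 180, rng.integers(3, 30))
            h[occ] = rng.integers(1, 1000, occ.size)
            k = int(rng.integers(1, 60))
            s0 = estimate_calcium_threshold(h)
            s1 = estimate_calcium_threshold(np.roll(h, k))
            assert s1.im_max == s0.im_max + k
            assert s1.t_calc_est == s0.t_calc_est + k
            assert s1.dr == s0.dr + k
            if s1.branch == s0.branch:
                assert s1.t_calc == pytest.approx(s0.t_calc + k)
            else:
                # dr - 0.7*im_max grows by 0.3k, so a shift can only flip the
                # branch dark -> bright, which raises the interpolation factor
                assert (s0.branch, s1.branch) == ("dark", "bright")
                assert s1.t_calc >= s0.t_calc + k
            tested += 1


class TestDetectCalcium:
    def _norm_img(self, data):
        return GrayImage(np.asarray(data, dtype=float), SP)

    def test_threshold_at_top_yields_empty_mask(self):
        img = self._norm_img(np.full((8, 8), 255.0))
        s = estimate_calcium_threshold(compute_histogram(img))
        # strict comparison: nothing is > 255
        assert s.t_calc == 255.0
        assert detect_calcium(img, s).count == 0

    def test_threshold_below_all_pixels_selects_everything(self):
        img = self._norm_img(np.full((8, 8), 10.0))
        s = estimate_calcium_threshold(compute_histogram(img))
        s.t_calc = 0.0
        assert detect_calcium(img, s).count == 64

    def test_phantom_calcium_recovered_across_noise_levels(self):
        from avaplan.phantom import PhantomSpec, generate_phantom

        for noise in (0.0, 2.5, 5.0):
            spec = PhantomSpec(
                noise_sd=noise,
                rng_seed=3,
                calcium_blobs=[((95.0, 120.0), 1.5), ((120.0, 95.0), 1.2), ((128.0, 128.0), 1.0)],
            )
            img, truth = generate_phantom(spec)
            region = sov_mod.detect_sov(img)
            crop = sov_mod.crop_image(img, region)
            norm = normalize_8bit(crop)
            s = estimate_calcium_threshold(compute_histogram(norm))
            mask = detect_calcium(norm, s)
            sl = (
                slice(region.row_start, region.row_stop),
                slice(region.col_start, region.col_stop),
            )
            truth_ca = truth.calcium_mask.data[sl]
            lumen_only = truth.sov_mask.data[sl] & ~truth_ca
            assert (mask.data & truth_ca).sum() == truth_ca.sum()  # mask ⊇ calcium
            contamination = (mask.data & lumen_only).sum() / lumen_only.sum()
            assert contamination <= 0.02
            # detected count close to truth once sub-deposit specks removed
            filtered = filter_calcium_mask(mask, 1.0)
            assert filtered.count == pytest.approx(truth_ca.sum(), rel=0.05)


def test_filter_calcium_mask_drops_specks_keeps_deposits():
    mask = np.zeros((40, 40), dtype=bool)
    mask[5, 5] = True                   # isolated noise pixel (0.25 mm²)
    mask[20:24, 20:24] = True           # 16 px = 4 mm² deposit
    out = filter_calcium_mask(BinaryMask(mask, SP), 1.0)
    assert out.count == 16
    assert out.data[20:24, 20:24].all()
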
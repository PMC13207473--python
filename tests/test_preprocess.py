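import numpy as np
import pytest

from octsaliency.preprocess import (
    AugmentConfig,
    ImageError,
    RawImage,
    StandardImage,
    augment,
    from_model_input,
    harmonize,
    standardize,
    to_model_input,
)


def _std(arr, side=None):
    from octsaliency.preprocess import LetterboxRecord

    arr = np.asarray(arr, dtype=float)
    s = side or arr.shape[0]
    return StandardImage(arr, LetterboxRecord(1.0, 0, 0, s, s))


class TestStandardize:
    def test_landscape_letterbox_geometry(self):
        raw = RawImage(np.random.default_rng(0).random((512, 1024)))
        std = standardize(raw)
        lb = std.letterbox
        assert (lb.rows, lb.cols) == (128, 256)
        assert lb.scale == 0.25
        assert (lb.row_offset, lb.col_offset) == (64, 0)
        # zero padding outside the content box
        assert np.all(std.gray[:64] == 0) and np.all(std.gray[192:] == 0)

    def test_identity_on_square_target_size(self):
        arr = np.random.default_rng(1).random((256, 256))
        std = standardize(RawImage(arr))
        assert std.letterbox.scale == 1.0
        assert np.allclose(std.gray, arr, atol=5e-3)  # Lanczos identity resize

    def test_odd_padding_goes_bottom(self):
        std = standardize(RawImage(np.ones((100, 300))))
        lb = std.letterbox
        assert (lb.rows, lb.cols) == (85, 256)  # round(100*256/300)
        assert lb.row_offset == 85  # (256-85)//2: extra padding pixel below
        assert np.all(std.gray[: lb.row_offset] == 0)
        assert np.all(std.gray[lb.row_offset + lb.rows :] == 0)

    @pytest.mark.parametrize("shape", [(8, 8), (13, 257), (300, 41), (1024, 9)])
    def test_aspect_ratio_preserved(self, shape):
        std = standardize(RawImage(np.ones(shape)))
        lb = std.letterbox
        # each content-box side is the exactly-scaled raw side within a pixel
        assert abs(lb.rows - shape[0] * lb.scale) <= 1.0
        assert abs(lb.cols - shape[1] * lb.scale) <= 1.0

    def test_aspect_ratio_random_shapes(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            h, w = rng.integers(8, 900, size=2)
            std = standardize(RawImage(np.zeros((h, w)) + 0.5))
            lb = std.letterbox
            assert abs(lb.rows - h * lb.scale) <= 1.0
            assert abs(lb.cols - w * lb.scale) <= 1.0
            assert max(lb.rows, lb.cols) == 256

    def test_multichannel_and_bitdepth(self):
        rgb = np.full((64, 64, 3), 255, dtype=np.uint8)
        std = standardize(RawImage(rgb))
        assert std.gray.max() <= 1.0 and std.gray[128, 128] == pytest.approx(1.0, abs=1e-6)
        u16 = np.full((64, 64), 65535, dtype=np.uint16)
        assert standardize(RawImage(u16)).gray.max() == pytest.approx(1.0, abs=1e-6)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ImageError):
            RawImage(np.ones((4, 100)))
        with pytest.raises(ImageError):
            RawImage(np.array([[np.nan] * 8] * 8))


class TestHarmonize:
    def test_constant_image_returns_zeros_with_warning(self):
        with pytest.warns(UserWarning):
            out = harmonize(_std(np.full((64, 64), 0.5)))
        assert np.all(out.gray == 0)

    def test_percentile_affine_rescale_on_ramp(self):
        ramp = np.tile(np.linspace(0, 1, 256), (256, 1))
        out = harmonize(_std(ramp), apply_clahe=False)
        lo, hi = np.percentile(ramp, [2, 98])
        interior = (ramp > lo) & (ramp < hi)
        assert np.allclose(out.gray[interior], (ramp[interior] - lo) / (hi - lo), atol=1e-12)
        assert out.gray.min() == 0.0 and out.gray.max() == 1.0

    def test_idempotent_without_clahe(self):
        rng = np.random.default_rng(3)
        img = harmonize(_std(rng.random((128, 128))), apply_clahe=False)
        again = harmonize(img, apply_clahe=False)
        # identity up to percentile interpolation at the clip boundary
        assert np.allclose(img.gray, again.gray, atol=1e-4)

    def test_output_spans_unit_interval(self):
        rng = np.random.default_rng(4)
        out = harmonize(_std(0.2 + 0.3 * rng.random((64, 64))))
        assert out.gray.min() == 0.0 and out.gray.max() == 1.0


class TestModelInput:
    def test_mean_cancellation(self):
        mi = to_model_input(_std(np.full((32, 32), 0.485)))
        assert np.allclose(mi.channels[0], 0.0, atol=1e-12)

    def test_channel_value(self):
        mi = to_model_input(_std(np.ones((32, 32))))
        assert mi.channels[0, 0, 0] == pytest.approx((1 - 0.485) / 0.229, abs=1e-6)

    def test_exact_inversion(self):
        rng = np.random.default_rng(5)
        std = _std(rng.random((32, 32)))
        assert np.allclose(from_model_input(to_model_input(std)), std.gray, atol=1e-6)

    def test_three_channels_one_plane(self):
        std = _std(np.random.default_rng(6).random((32, 32)))
        mi = to_model_input(std)
        recovered = [mi.channels[c] * mi.std[c] + mi.mean[c] for c in range(3)]
        assert np.allclose(recovered[0], recovered[1]) and np.allclose(recovered[1], recovered[2])


class TestAugment:
    def _noop_cfg(self, seed=0):
        return AugmentConfig(flip_p=0, max_rotation_deg=0, max_translate_frac=0,
                             scale_range=(1, 1), brightness_contrast_jitter=0,
                             gamma_p=0, blur_p=0, seed=seed)

    def test_noop_config_is_identity(self):
        std = _std(np.random.default_rng(7).random((64, 64)))
        out = augment(std, self._noop_cfg())
        assert np.array_equal(out.gray, std.gray)

    def test_same_seed_bit_identical(self):
        std = _std(np.random.default_rng(8).random((64, 64)))
        cfg = AugmentConfig(seed=123)
        a = augment(std, cfg)
        b = augment(std, cfg)
        assert np.array_equal(a.gray, b.gray)

    def test_double_flip_is_involution(self):
        std = _std(np.random.default_rng(9).random((64, 64)))
        cfg = AugmentConfig(flip_p=1.0, max_rotation_deg=0, max_translate_frac=0,
                            scale_range=(1, 1), brightness_contrast_jitter=0,
                            gamma_p=0, blur_p=0, seed=1)
        out = augment(augment(std, cfg), cfg)
        assert np.allclose(out.gray, std.gray)

    def test_output_stays_in_unit_interval(self):
        std = _std(np.random.default_rng(10).random((64, 64)))
        for seed in range(10):
            out = augment(std, AugmentConfig(seed=seed))
            assert out.gray.min() >= 0.0 and out.gray.max() <= 1.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            AugmentConfig(flip_p=1.5)
        with pytest.raises(ValueError):
            AugmentConfig(scale_range=(1.2, 0.9))
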
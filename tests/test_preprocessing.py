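"""Image pipeline (denoise, suppression, resize) and feature preparation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from qhandpd import preprocessing as pp
from qhandpd.io import FEATURE_COLUMNS


def _img(arr):
    return np.asarray(arr, dtype=np.uint8)


class TestDenoise:
    def test_kernel_one_is_identity(self, rng):
        img = _img(rng.integers(0, 256, (8, 8, 3)))
        assert np.array_equal(pp.denoise(img, 1, 1), img)

    def test_constant_image_unchanged(self):
        img = _img(np.full((6, 6, 3), 120))
        assert np.array_equal(pp.denoise(img), img)

    def test_salt_pixel_removed_by_median(self):
        img = _img(np.full((7, 7, 3), 100))
        img[3, 3] = 255
        out = pp.denoise(img, mean_kernel=1, median_kernel=3)
        assert np.all(out[3, 3] == 100)

    @pytest.mark.parametrize("bad", [0, 2, 4])
    def test_even_or_zero_kernels_rejected(self, bad):
        img = _img(np.zeros((4, 4, 3)))
        with pytest.raises(ValueError):
            pp.denoise(img, mean_kernel=bad)


class TestSuppression:
    def test_gray_pixel_whitened(self):
        img = _img([[[100, 100, 100]]])
        assert np.array_equal(pp.suppress_grayscale(img)[0, 0],
                              [255, 255, 255])

    def test_saturated_pixel_kept(self):
        img = _img([[[200, 100, 30]]])
        assert np.array_equal(pp.suppress_grayscale(img)[0, 0],
                              [200, 100, 30])

    def test_strict_inequality_boundary(self):
        kept = _img([[[100, 145, 100]]])       # |R-G| = 45, not < 45
        gone = _img([[[100, 144, 100]]])       # |R-G| = 44 < 45
        assert np.array_equal(pp.suppress_grayscale(kept)[0, 0],
                              [100, 145, 100])
        assert np.array_equal(pp.suppress_grayscale(gone)[0, 0],
                              [255, 255, 255])

    def test_idempotent(self, rng):
        img = _img(rng.integers(0, 256, (16, 16, 3)))
        once = pp.suppress_grayscale(img)
        assert np.array_equal(pp.suppress_grayscale(once), once)

    def test_suppressed_count_monotone_in_threshold(self, rng):
        img = _img(rng.integers(0, 256, (32, 32, 3)))
        counts = []
        for t in (10, 45, 90, 200, 255):
            out = pp.suppress_grayscale(img, t)
            counts.append(int((out == 255).all(axis=2).sum()))
        assert np.all(np.diff(counts) >= 0)

    @pytest.mark.parametrize("bad", [0, -5, 256, 400])
    def test_invalid_threshold_rejected(self, bad):
        with pytest.raises(ValueError):
            pp.suppress_grayscale(_img(np.zeros((2, 2, 3))), bad)


class TestResize:
    def test_same_size_only_rescales(self, rng):
        img = _img(rng.integers(0, 256, (512, 512, 3)))
        out = pp.resize_and_scale(img)
        assert out.shape == (512, 512, 3)
        assert np.allclose(out, img / 255.0)

    def test_downscaling_shape(self, rng):
        img = _img(rng.integers(0, 256, (1024, 1024, 3)))
        assert pp.resize_and_scale(img).shape == (512, 512, 3)

    def test_all_white_maps_to_ones(self):
        img = _img(np.full((64, 64, 3), 255))
        assert np.allclose(pp.resize_and_scale(img, 32), 1.0)

    def test_bad_side_rejected(self):
        with pytest.raises(ValueError):
            pp.resize_and_scale(_img(np.zeros((4, 4, 3))), 0)


def _records(**overrides):
    base = pd.DataFrame({
        "gender": ["M", "F", "M"], "handedness": ["R", "R", "L"],
        "age": [40.0, np.nan, 60.0], "rms": [1.0, 2.0, 3.0],
        "mrt": [0.1, 0.2, 0.3], "std_diff": [0.5, 0.5, 0.5]})
    for k, v in overrides.items():
        base[k] = v
    return base


class TestImputation:
    def test_no_missing_is_identity(self):
        df = _records(age=[40.0, 50.0, 60.0])
        out, _ = pp.impute_features(df)
        assert np.allclose(out["age"], [40, 50, 60])

    def test_missing_age_gets_column_mean(self):
        out, stats = pp.impute_features(_records())
        assert out["age"].iloc[1] == pytest.approx(50.0)
        assert stats["age"] == pytest.approx(50.0)

    def test_train_statistics_applied_to_test(self):
        _, stats = pp.impute_features(_records(age=[10.0, 20.0, 30.0]))
        test = _records(age=[np.nan, np.nan, np.nan])
        out, _ = pp.impute_features(test, stats)
        assert np.allclose(out["age"], 20.0)

    def test_fully_missing_column_rejected(self):
        with pytest.raises(ValueError):
            pp.impute_features(_records(rms=[np.nan] * 3))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pp.impute_features(_records().iloc[:0])


class TestNormalization:
    def test_endpoints_and_midpoint(self):
        df = _records(age=[40.0, 50.0, 60.0])
        pipe = pp.FeaturePipeline().fit(df)
        out = pipe.transform(df)
        j = FEATURE_COLUMNS.index("age")
        assert np.allclose(out[:, j], [0.0, np.pi / 2, np.pi])

    def test_constant_column_maps_to_zero(self):
        df = _records()
        pipe = pp.FeaturePipeline().fit(df)
        j = FEATURE_COLUMNS.index("std_diff")
        assert np.allclose(pipe.transform(df)[:, j], 0.0)

    def test_out_of_range_test_value_clipped(self):
        train = _records(age=[40.0, 50.0, 60.0])
        pipe = pp.FeaturePipeline().fit(train)
        test = _records(age=[100.0, -5.0, 50.0])
        j = FEATURE_COLUMNS.index("age")
        col = pipe.transform(test)[:, j]
        assert col[0] == pytest.approx(np.pi)
        assert col[1] == pytest.approx(0.0)

    def test_unfitted_pipeline_rejected(self):
        with pytest.raises(RuntimeError):
            pp.FeaturePipeline().transform(_records())

    @settings(max_examples=25, deadline=None)
    @given(ages=st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=6),
           rms=st.lists(st.floats(0, 1e3), min_size=2, max_size=6))
    def test_output_always_in_valid_range(self, ages, rms):
        n = min(len(ages), len(rms))
        df = pd.DataFrame({
            "gender": ["M"] * n, "handedness": ["R"] * n,
            "age": ages[:n], "rms": rms[:n],
            "mrt": [0.1] * n, "std_diff": [0.2] * n})
        out = pp.FeaturePipeline().fit_transform(df)
        assert np.all(out >= 0.0) and np.all(out <= np.pi)


def test_full_image_pipeline_shapes_and_range(tiny_manifest):
    from qhandpd.io import load_image
    img = load_image(tiny_manifest.records["image_path"].iloc[0])
    out = pp.preprocess_image(img, side=128)
    assert out.shape == (128, 128, 3)
    assert out.min() >= 0.0 and out.max() <= 1.0
    assert (out < 0.99).any()     # the pen trace survives
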
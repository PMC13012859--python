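"""Derived images, histogram/shape/first-order features, catalogue."""

import numpy as np
import pytest
from skimage.draw import disk, ellipse

from crferad.features import (
    FeatureConfig,
    build_catalogue,
    extract_all,
    first_order_features,
    histogram_features,
    shape_features,
)
from crferad.filters import DERIVED_KINDS, DerivedImage, derive_images


class TestDerivedImages:
    def test_count_and_kinds(self, rng):
        out = derive_images(rng.normal(size=(32, 32)), spacing=1.0)
        assert len(out) == 9
        assert tuple(d.kind for d in out) == DERIVED_KINDS

    def test_log_of_constant_is_zero(self):
        # zero up to the sampled-kernel discretization error
        out = {d.kind: d.data for d in derive_images(np.full((32, 32), 2.0), 1.0)}
        assert np.allclose(out["log-sigma-1.0mm"], 0.0, atol=1e-5)
        assert np.allclose(out["log-sigma-2.0mm"], 0.0, atol=1e-10)

    def test_sqrt_square_inverse_pair_on_nonnegative(self, rng):
        img = rng.random((16, 16)) + 0.5
        root = {d.kind: d.data for d in derive_images(img, 1.0)}["square-root"]
        squared = {d.kind: d.data for d in derive_images(root, 1.0)}["square"]
        assert np.allclose(squared, img, atol=1e-10)

    def test_all_finite_including_log_of_negatives(self, rng):
        img = rng.normal(size=(16, 16)) * 100
        for d in derive_images(img, 0.5):
            assert np.isfinite(d.data).all(), d.kind

    def test_wavelet_lowpass_plus_detail_reconstructs(self, rng):
        img = rng.normal(size=(32, 32))
        out = {d.kind: d.data for d in derive_images(img, 1.0)}
        assert np.allclose(out["wavelet-L"] + out["wavelet-H"], img, atol=1e-8)


class TestHistogramFeatures:
    def test_median_of_small_sample(self):
        f = histogram_features(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert f["histogram_Median"] == 3.0
        assert list(f)[0] == "histogram_Median"  # the named biomarker first

    def test_constant_region_degenerate(self):
        f = histogram_features(np.full(50, 2.0))
        assert f["histogram_Variance"] == 0.0
        assert f["histogram_Entropy"] == 0.0

    def test_standard_normal_sampling_moments(self, rng):
        x = rng.normal(size=1000)
        f = histogram_features(x)
        assert abs(f["histogram_Skewness"]) < 0.25
        assert f["histogram_Mean"] == pytest.approx(x.mean())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            histogram_features(np.array([]))


class TestShapeFeatures:
    def test_disk_circularity_near_one(self):
        mask = np.zeros((64, 64), dtype=np.uint8)
        rr, cc = disk((32, 32), 22)
        mask[rr, cc] = 1
        f = shape_features(mask, spacing=1.0)
        assert f["shape_Sphericity"] == pytest.approx(1.0, abs=0.03)

    def test_two_to_one_ellipse_elongation(self):
        mask = np.zeros((128, 128), dtype=np.uint8)
        rr, cc = ellipse(64, 64, 20, 40)
        mask[rr, cc] = 1
        f = shape_features(mask, spacing=1.0)
        assert f["shape_Elongation"] == pytest.approx(0.5, rel=0.05)

    def test_scaling_doubles_diameters_keeps_elongation(self):
        mask = np.zeros((128, 128), dtype=np.uint8)
        rr, cc = ellipse(40, 40, 10, 20)
        mask[rr, cc] = 1
        big = np.zeros((128, 128), dtype=np.uint8)
        rr, cc = ellipse(64, 64, 20, 40)
        big[rr, cc] = 1
        f1, f2 = shape_features(mask, 1.0), shape_features(big, 1.0)
        assert f2["shape_MajorAxisLength"] == pytest.approx(
            2 * f1["shape_MajorAxisLength"], rel=0.03
        )
        assert f2["shape_MaximumDiameter"] == pytest.approx(
            2 * f1["shape_MaximumDiameter"], rel=0.03
        )
        assert f2["shape_Elongation"] == pytest.approx(f1["shape_Elongation"], rel=0.05)

    def test_feature_count(self, phantom64):
        ph, cfg = phantom64
        assert len(shape_features(ph.mask, cfg.pixel_spacing)) == 14


class TestFirstOrderFeatures:
    def test_constant_region(self):
        d = DerivedImage("original", np.full((8, 8), 3.0))
        f = first_order_features(d, np.ones((8, 8), bool))
        p = "original_firstorder_"
        assert f[p + "Mean"] == f[p + "Median"] == f[p + "RootMeanSquared"] == 3.0
        assert f[p + "Variance"] == 0.0

    def test_symmetric_two_point_region(self):
        data = np.array([[-1.0, 1.0]] * 4)
        f = first_order_features(DerivedImage("original", data), np.ones((4, 2), bool))
        assert f["original_firstorder_RootMeanSquared"] == 1.0
        assert f["original_firstorder_Mean"] == 0.0

    def test_count_is_eighteen(self, rng):
        d = DerivedImage("square", rng.normal(size=(8, 8)))
        assert len(first_order_features(d, np.ones((8, 8), bool))) == 18


class TestCatalogue:
    def test_total_and_family_counts(self):
        cat = build_catalogue()
        assert len(cat) == 868
        counts = cat.family_counts()
        assert counts == {
            "clinical": 8, "shape": 14, "histogram": 9, "firstorder": 162,
            "glcm": 216, "glrlm": 144, "glszm": 144, "gldm": 126, "ngtdm": 45,
        }

    def test_names_unique_and_ordered(self):
        cat = build_catalogue()
        assert len(set(cat.names)) == len(cat)
        assert cat.names[0].startswith("clinical_")

    def test_extract_matches_catalogue_and_is_deterministic(self, phantom64):
        ph, cfg = phantom64
        fc = FeatureConfig(pixel_spacing=cfg.pixel_spacing)
        v1 = extract_all(ph, fc)
        v2 = extract_all(ph, fc)
        assert list(v1) == build_catalogue(fc).names
        assert v1 == v2
        assert all(np.isfinite(x) for x in v1.values())
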